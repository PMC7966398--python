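"""Pfaffl relative quantification of RT-qPCR fold changes.

FC = E_target^dCt_target / E_ref^dCt_ref, where dCt = Ct(control) -
Ct(treated) and E is the assay amplification efficiency (1 = no
amplification per cycle, 2 = perfect doubling). With E = 2 for both
assays the expression reduces to the familiar 2^-ddCt convention, which
is the default when efficiencies are not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from coexmod.errors import ConfigurationError, DataError


@dataclass(frozen=True)
class PfafflInput:
    e_target: float     # target assay efficiency, in [1, 2]
    e_ref: float        # reference assay efficiency, in [1, 2]
    dct_target: float   # Ct(control) - Ct(treated) for the target, cycles
    dct_ref: float      # Ct(control) - Ct(treated) for the reference, cycles

    def validate(self) -> None:
        for name, e in (("e_target", self.e_target), ("e_ref", self.e_ref)):
            if not 1.0 <= e <= 2.0:
                raise ConfigurationError(f"{name}={e} outside the valid range [1, 2]")


def pfaffl_fold_change(x: PfafflInput) -> float:
    x.validate()
    return x.e_target**x.dct_target / x.e_ref**x.dct_ref


def fold_changes_from_table(
    table: pd.DataFrame | str | Path,
    reference_gene: str,
    control_group: str,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> pd.DataFrame:
    """Per-gene, per-group Pfaffl fold changes from a Ct table.

    The table (DataFrame or TSV path) has columns sample, gene, ct, group.
    For each non-control group and each gene other than the reference,
    dCt is the difference of group-mean Ct values (control minus treated)
    and the fold change is Pfaffl-normalized to the reference gene.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t")
    required = {"sample", "gene", "ct", "group"}
    if not required <= set(table.columns):
        raise DataError(f"Ct table needs columns {sorted(required)}")
    if reference_gene not in set(table["gene"]):
        raise DataError(f"reference gene {reference_gene!r} absent from the table")
    if control_group not in set(table["group"]):
        raise DataError(f"control group {control_group!r} absent from the table")

    mean_ct = table.groupby(["gene", "group"])["ct"].mean()
    rows = []
    groups = [g for g in table["group"].unique() if g != control_group]
    genes = [g for g in table["gene"].unique() if g != reference_gene]
    for group in groups:
        dct_ref = mean_ct[(reference_gene, control_group)] - mean_ct[(reference_gene, group)]
        for gene in genes:
            if (gene, group) not in mean_ct.index or (gene, control_group) not in mean_ct.index:
                continue
            dct_t = mean_ct[(gene, control_group)] - mean_ct[(gene, group)]
            fc = pfaffl_fold_change(PfafflInput(e_target, e_ref, dct_t, dct_ref))
            rows.append({"gene": gene, "group": group, "dct_target": dct_t,
                         "dct_ref": dct_ref, "fold_change": fc})
    return pd.DataFrame(rows, columns=["gene", "group", "dct_target", "dct_ref", "fold_change"])
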