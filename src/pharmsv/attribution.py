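"""Share of genetically encoded pharmacogenomic variability from non-coding SVs.

The attribution is a simple count-based fraction over per-individual
functional variant burdens:

    func_ncSV = n_ncSV / (n_ncSV + n_SNV + n_cSV)

with n_ncSV the number of functional non-coding SVs per individual (TFBS
hits with co-expression support), n_cSV the functional exonic SVs (LOF +
IGD, ADME genes plus drug targets) and n_SNV the functional SNV count per
individual, a literature-supplied constant (defaults: 40.6 for ADME genes,
26.0 for drug targets), never computed here.
"""
from __future__ import annotations

from dataclasses import dataclass

DEFAULT_N_SNV_ADME = 40.6
DEFAULT_N_SNV_TARGETS = 26.0


@dataclass(frozen=True)
class VariabilityComponents:
    """Per-individual functional variant counts feeding the attribution."""

    n_ncsv: float  # functional non-coding SVs
    n_csv: float   # functional exonic SVs (ADME + drug targets)
    n_snv: float   # functional SNVs (externally supplied)

    def __post_init__(self):
        if min(self.n_ncsv, self.n_csv, self.n_snv) < 0:
            raise ValueError("components must be non-negative")
        if self.n_ncsv + self.n_csv + self.n_snv == 0:
            raise ValueError("all components zero: fraction undefined")


def attribute_variability(components: VariabilityComponents) -> float:
    """Fraction of variability attributable to non-coding SVs, in [0, 1]."""
    denom = components.n_ncsv + components.n_snv + components.n_csv
    return components.n_ncsv / denom


def noncoding_share(
    n_ncsv: float,
    n_csv_adme: float,
    n_csv_targets: float,
    n_snv_adme: float = DEFAULT_N_SNV_ADME,
    n_snv_targets: float = DEFAULT_N_SNV_TARGETS,
) -> float:
    """Convenience wrapper assembling the components from per-panel counts."""
    comps = VariabilityComponents(
        n_ncsv=n_ncsv,
        n_csv=n_csv_adme + n_csv_targets,
        n_snv=n_snv_adme + n_snv_targets,
    )
    return attribute_variability(comps)
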