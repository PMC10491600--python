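"""Per-individual SV burdens and Hardy-Weinberg carrier simulation.

The burden of a set of functional SVs is the expected diploid allele
dosage per individual, sum over loci of 2*AF, grouped by gene class and
functional class; an alternative carrier-probability metric
(sum of 1-(1-AF)^2) is available behind ``metric="carrier"``.  Carrier
frequencies are estimated by simulating diploid cohorts (default 100,000
individuals) with independent loci in Hardy-Weinberg equilibrium and are
reported in the conventional "1 in N individuals" form.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedSV, FunctionalClass
from .genome_model import panel_group

FUNCTIONAL_CLASSES = (FunctionalClass.LOF, FunctionalClass.IGD)


@dataclass
class BurdenReport:
    """Expected per-individual functional-SV counts for one population."""

    population: str
    metric: str
    #: per-SV contribution rows (sv_id, gene, classes, af, contribution)
    contributions: pd.DataFrame
    #: skipped because the population frequency was absent
    n_skipped: int = 0

    @property
    def table(self) -> pd.DataFrame:
        """Totals per (gene-class group, functional class)."""
        if self.contributions.empty:
            return pd.DataFrame(columns=["panel_group", "functional_class", "burden"])
        return (
            self.contributions
            .groupby(["panel_group", "functional_class"], as_index=False)["contribution"]
            .sum()
            .rename(columns={"contribution": "burden"})
        )

    def total(self, group: str | None = None,
              functional_class: str | None = None) -> float:
        df = self.contributions
        if group is not None:
            df = df[df["panel_group"] == group]
        if functional_class is not None:
            df = df[df["functional_class"] == functional_class]
        return float(df["contribution"].sum())


def _contribution(af: float, metric: str) -> float:
    if metric == "dosage":
        return 2.0 * af
    if metric == "carrier":
        return 1.0 - (1.0 - af) ** 2
    raise ValueError(f"unknown burden metric {metric!r}")


def expected_burden(
    annotated: Sequence[AnnotatedSV],
    population: str = "global",
    classes: tuple[FunctionalClass, ...] = FUNCTIONAL_CLASSES,
    metric: str = "dosage",
) -> BurdenReport:
    """Expected functional-SV burden per individual for one population.

    Only SVs with a functional class in ``classes`` (default LOF and IGD)
    contribute.  MCNV loci enter through their decomposed deletion-like /
    duplication-like components, which carry their own frequencies.  SVs
    lacking a frequency for the requested population are skipped and
    counted.
    """
    rows = []
    skipped = 0
    for a in annotated:
        if a.functional_class not in classes:
            continue
        if population == "global":
            af = a.af
        else:
            af = a.af_by_pop.get(population)
        if af is None:
            skipped += 1
            continue
        rows.append({
            "sv_id": a.sv_id, "gene_id": a.gene_id,
            "panel_class": a.panel_class, "panel_group": panel_group(a.panel_class),
            "functional_class": a.functional_class.value,
            "component": a.component or "", "af": af,
            "contribution": _contribution(af, metric),
        })
    cols = ["sv_id", "gene_id", "panel_class", "panel_group",
            "functional_class", "component", "af", "contribution"]
    return BurdenReport(
        population=population, metric=metric,
        contributions=pd.DataFrame(rows, columns=cols), n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class SimulatedCohort:
    """Diploid cohort simulated under HWE with independent loci."""

    n_individuals: int
    seed: int
    per_sv: pd.DataFrame  # sv_id, af, carriers, homozygotes
    #: mean number of alternate alleles per individual, summed over loci
    mean_alleles_per_individual: float

    def carrier_fraction(self, sv_id: str) -> float:
        row = self.per_sv.loc[self.per_sv["sv_id"] == sv_id]
        if row.empty:
            raise KeyError(sv_id)
        return float(row["carriers"].iloc[0]) / self.n_individuals


def simulate_cohort(
    svs: Sequence[tuple[str, float]] | dict[str, float],
    n: int = 100_000,
    seed: int = 1,
) -> SimulatedCohort:
    """Simulate ``n`` diploid individuals at independent loci under HWE.

    Each individual draws two alleles per locus (binomial with the locus
    allele frequency); a carrier has >= 1 alternate allele.  Reproducible
    for a given seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    items = list(svs.items()) if isinstance(svs, dict) else list(svs)
    rng = np.random.default_rng(seed)
    rows = []
    total_alleles = 0
    for sv_id, af in items:
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"{sv_id}: frequency {af} outside [0, 1]")
        genotypes = rng.binomial(2, af, size=n)
        carriers = int((genotypes > 0).sum())
        hom = int((genotypes == 2).sum())
        total_alleles += int(genotypes.sum())
        rows.append({"sv_id": sv_id, "af": af, "carriers": carriers,
                     "homozygotes": hom})
    per_sv = pd.DataFrame(rows, columns=["sv_id", "af", "carriers", "homozygotes"])
    return SimulatedCohort(
        n_individuals=n, seed=seed, per_sv=per_sv,
        mean_alleles_per_individual=total_alleles / n,
    )


def carrier_ratio(carrier_fraction: float) -> str:
    """Report a carrier fraction as "1 in N individuals".

    N = round(1 / fraction); fractions >= 0.75 round to one carrier per
    individual and are reported as such; a zero fraction reports "0".
    """
    if carrier_fraction == 0:
        return "0"
    if not (0.0 < carrier_fraction <= 1.0):
        raise ValueError(f"carrier fraction {carrier_fraction} outside (0, 1]")
    if carrier_fraction >= 0.75:
        return "1 per individual"
    return f"1 in {round(1.0 / carrier_fraction)}"
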