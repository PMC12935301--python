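"""Seeded synthetic variant cohorts with the statistical structure the
pipeline assumes, so every stage is testable without external data.

A cohort mimics the study conditions: residues uniform over the 1912-aa
protein, a fixed fraction of pathogenic-class variants, class-conditional
predictor scores drawn from Beta distributions (pathogenic Beta(8, 2),
benign Beta(2, 8) by default), de novo evidence (PS2) at the study's >90%
de novo prevalence, PM2 exactly per the population-frequency rule (absent or
AF <= 0.001), PP3/BP4 derived from the simulated REVEL score through the
calibration module, and heart-anomaly probabilities that depend on whether
the variant falls in the ATPase motor region (defaults 0.95 inside vs. 0.60
elsewhere, mirroring the observed 19/20 and 9/15 group rates).

Randomness: one ``numpy.random.default_rng`` stream per cohort, seeded from
``CohortSpec.seed``; draws occur variant by variant in a fixed documented
order (class, residue, ref/alt residues, four scores, allele frequency,
de novo status, heart anomaly), so outputs are reproducible across runs.
Replicate streams in :func:`power_of_enrichment` come from
``numpy.random.SeedSequence(seed).spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .calibration import CalibrationTable, DEFAULT_CALIBRATION, revel_to_evidence
from .domain_architecture import DomainArchitecture, load_chd4_architecture
from .enrichment_stats import ContingencyTable2x2, fisher_exact_two_sided
from .variant_model import AMINO_ACIDS, CHD4_LENGTH

__all__ = ["CohortSpec", "generate", "power_of_enrichment"]

_SCORE_COLS = ("metarnn", "polyphen2", "alphamissense", "revel")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror the study conditions."""

    n_variants: int = 36
    seed: int = 0
    prop_pathogenic: float = 0.75
    #: heart-anomaly probability inside the named region vs. elsewhere
    region: str = "ATPase_motor_region"
    region_anomaly_prob: float = 0.95
    other_anomaly_prob: float = 0.60
    de_novo_prob: float = 0.9
    #: class-conditional Beta score parameters (same for all four tools)
    beta_pathogenic: tuple[float, float] = (8.0, 2.0)
    beta_benign: tuple[float, float] = (2.0, 8.0)
    #: benign variants draw a log-uniform allele frequency over this range;
    #: pathogenic variants are absent from the population database
    af_range: tuple[float, float] = (1e-6, 1e-2)
    af_threshold: float = 0.001  # PM2 rule

    def __post_init__(self) -> None:
        for p in (self.prop_pathogenic, self.region_anomaly_prob,
                  self.other_anomaly_prob, self.de_novo_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(*self.beta_pathogenic, *self.beta_benign) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")


def generate(spec: CohortSpec,
             arch: DomainArchitecture | None = None,
             calibration: CalibrationTable = DEFAULT_CALIBRATION) -> pd.DataFrame:
    """Generate a synthetic variant table (same TSV schema as the fixture).

    Deterministic given ``spec.seed``.  Returns a DataFrame ready to be
    written with ``DataFrame.to_csv(sep="\\t")`` and read back by
    ``read_variant_table``; an extra ``true_class`` column records the
    simulated class label.
    """
    if arch is None:
        arch = load_chd4_architecture()
    region = arch[spec.region]
    rng = np.random.default_rng(spec.seed)
    rows = []
    for _ in range(spec.n_variants):
        pathogenic = bool(rng.random() < spec.prop_pathogenic)
        pos = int(rng.integers(1, CHD4_LENGTH + 1))
        ref, alt = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        a, b = spec.beta_pathogenic if pathogenic else spec.beta_benign
        scores = {tool: float(rng.beta(a, b)) for tool in _SCORE_COLS}
        if pathogenic:
            af = None
        else:
            lo, hi = np.log(spec.af_range)
            af = float(np.exp(rng.uniform(lo, hi)))
        de_novo = bool(rng.random() < spec.de_novo_prob)
        p_anom = spec.region_anomaly_prob if region.intersects(pos, pos) \
            else spec.other_anomaly_prob
        anomaly = "yes" if rng.random() < p_anom else "no"

        evidence = []
        if de_novo:
            evidence.append("PS2")
        if af is None or af <= spec.af_threshold:
            evidence.append("PM2")
        comp = revel_to_evidence(scores["revel"], calibration)
        if comp is not None:
            evidence.append(str(comp))
        rows.append({
            "variant": f"p.{ref}{pos}{alt}",
            "type": "missense",
            "cdna": "",
            **{tool: format(scores[tool], ".6f") for tool in _SCORE_COLS},
            "evidence": "+".join(evidence),
            "gnomad_af": "" if af is None else format(af, ".3e"),
            "clinvar": "NP",
            "heart_anomaly": anomaly,
            "diseases": "",
            "syndrome": "other",
            "true_class": "pathogenic" if pathogenic else "benign",
        })
    columns = ["variant", "type", "cdna", *_SCORE_COLS, "evidence", "gnomad_af",
               "clinvar", "heart_anomaly", "diseases", "syndrome", "true_class"]
    return pd.DataFrame(rows, columns=columns)


def power_of_enrichment(spec: CohortSpec, n_reps: int, alpha: float = 0.05,
                        group_sizes: tuple[int, int] | None = None) -> float:
    """Monte-Carlo fraction of replicates with a significant Fisher test.

    Each replicate draws heart-anomaly outcomes for a region group and an
    other-domain group and applies the two-sided Fisher exact test at level
    ``alpha``.  With ``group_sizes=(n_region, n_other)`` the group sizes are
    fixed (the study design is 20 vs. 15); otherwise each of
    ``spec.n_variants`` variants falls in the region with probability equal
    to the region's share of the protein, as under :func:`generate`.
    Replicates with a degenerate table (zero margin) count as non-rejections
    (their p-value is one).  Seeded and reproducible via ``spec.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    region_len = None
    if group_sizes is None:
        arch = load_chd4_architecture()
        region_len = arch[spec.region].length
    rejections = 0
    streams = np.random.SeedSequence(spec.seed).spawn(n_reps)
    for ss in streams:
        rng = np.random.default_rng(ss)
        if group_sizes is not None:
            n1, n2 = group_sizes
        else:
            n1 = int(rng.binomial(spec.n_variants, region_len / CHD4_LENGTH))
            n2 = spec.n_variants - n1
        a = int(rng.binomial(n1, spec.region_anomaly_prob)) if n1 else 0
        c = int(rng.binomial(n2, spec.other_anomaly_prob)) if n2 else 0
        if n1 + n2 == 0:
            p = 1.0
        else:
            t = ContingencyTable2x2(a, n1 - a, c, n2 - c)
            p = 1.0 if 0 in t.margins else fisher_exact_two_sided(t)
        if p < alpha or alpha >= 1.0:
            rejections += 1
    return rejections / n_reps
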