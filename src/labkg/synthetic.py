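"""Synthetic reference ranges and patient cohorts with known ground truth.

Real hospital exam panels are not redistributable, so every pipeline
stage is exercised on generated data whose disease mechanism is known
exactly.  The generator mirrors the structure of a clinical exam dataset:
m continuous indicators with published normal ranges, heavy class
imbalance (about 1 diseased : 9 healthy by default), missing cells, and a
label driven by how far measurements deviate from their normal ranges.

Mechanism: each patient carries a latent disease state z.  Healthy
values are drawn near the middle of the reference range (occasionally
drifting slightly outside, as real healthy values do); in diseased
patients the *causal* indicators are shifted above the range.  Every
value is then assigned an integer severity s in {-3..+3} by the same
seven-band rule the knowledge graph uses (normal = 0, severely high = +3),
and the label is Bernoulli(sigmoid(beta0 + sum_j beta_j s_j)).  Large
betas saturate the sigmoid and make labels a deterministic function of
the values, which gives a known Bayes ceiling for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .encoder import PatientRecord
from .kg import BANDS, BandParams, ReferenceRange, band_of

__all__ = [
    "CohortSpec",
    "gen_ranges",
    "gen_cohort",
    "expected_bayes_accuracy",
    "strong_signal_spec",
    "write_cohort",
]

_SEVERITY = {band: i - 3 for i, band in enumerate(BANDS)}  # severely_low=-3 .. severely_high=+3


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for one cohort.

    ``betas[j]`` is the log-odds contribution of one severity step of
    indicator j; ``causal_set`` lists the indicator indices with nonzero
    effect.  ``prevalence`` is the latent disease probability (default
    0.10, i.e. roughly 1:9 positives:negatives).
    """

    m: int
    n: int
    beta0: float
    betas: tuple[float, ...]
    causal_set: tuple[int, ...]
    missing_rate: float = 0.05
    prevalence: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.betas) != self.m:
            raise ValueError(f"need {self.m} betas, got {len(self.betas)}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if any(j < 0 or j >= self.m for j in self.causal_set):
            raise ValueError("causal_set indices out of range")


def strong_signal_spec(n: int = 4000, m: int = 11, seed: int = 7) -> CohortSpec:
    """The canonical recovery cohort: 3 causal indicators with saturated
    effects (labels deterministic given the values), balanced classes, no
    missing cells."""
    # up to three causal indicators, spread across the panel ((1, 4, 8)
    # for the default m = 11)
    causal = tuple(sorted({(1 * m) // 11, (4 * m) // 11, (8 * m) // 11}))
    betas = tuple(20.0 if j in causal else 0.0 for j in range(m))
    return CohortSpec(
        m=m, n=n, beta0=-30.0, betas=betas, causal_set=causal,
        missing_rate=0.0, prevalence=0.5, seed=seed,
    )


def gen_ranges(m: int, seed: int = 0) -> list[ReferenceRange]:
    """m plausible reference ranges: lower bound uniform(0.5, 50), width
    uniform(20%, 150%) of the lower bound, default grid policy."""
    if m < 1:
        raise ValueError("need at least one indicator")
    rng = np.random.default_rng(seed)
    out = []
    for j in range(m):
        low = round(float(rng.uniform(0.5, 50.0)), 2)
        width = round(float(low * rng.uniform(0.2, 1.5)), 2)
        out.append(
            ReferenceRange(
                indicator=f"indicator_{j:02d}",
                low=low,
                high=round(low + max(width, 0.01), 2),
                units="mmol/L",
            )
        )
    return out


def gen_cohort(
    ranges: list[ReferenceRange],
    spec: CohortSpec,
    bands: BandParams = BandParams(),
) -> tuple[list[PatientRecord], np.ndarray, dict]:
    """Draw a cohort; returns (records, labels, latent truth).

    The truth dict holds the full value matrix before masking, the
    per-cell severities, the true sigmoid probabilities and the latent
    disease states, for oracle checks.  Deterministic given ``spec.seed``.
    """
    if len(ranges) != spec.m:
        raise ValueError(f"spec.m={spec.m} but {len(ranges)} ranges supplied")
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m
    z = rng.random(n) < spec.prevalence

    values = np.empty((n, m))
    for j, r in enumerate(ranges):
        w = r.width
        mid = 0.5 * (r.low + r.high)
        base = rng.normal(mid, w / 5.0, size=n)
        if j in spec.causal_set:
            # diseased: shift above the range by 0.25-1.125 range-widths,
            # i.e. generally-high to severely-high under default bands
            dev = rng.uniform(bands.alpha1, bands.alpha2 * 1.5, size=n) * w
            base = np.where(z, r.high + dev, base)
        if r.nonnegative:
            base = np.maximum(base, 0.0)
        values[:, j] = base

    severities = np.empty((n, m), dtype=int)
    for j, r in enumerate(ranges):
        severities[:, j] = [_SEVERITY[band_of(v, r, bands)] for v in values[:, j]]

    eta = spec.beta0 + severities @ np.asarray(spec.betas)
    probs = expit(eta)
    labels = (rng.random(n) < probs).astype(int)

    missing = rng.random((n, m)) < spec.missing_rate
    records = []
    for i in range(n):
        vals = {
            r.indicator: (None if missing[i, j] else float(values[i, j]))
            for j, r in enumerate(ranges)
        }
        records.append(PatientRecord(values=vals, label=int(labels[i])))

    truth = {
        "values": values,
        "severities": severities,
        "probs": probs,
        "latent": z.astype(int),
        "missing": missing,
    }
    return records, labels, truth


def expected_bayes_accuracy(labels: np.ndarray, truth: dict) -> float:
    """Accuracy of the optimal rule that thresholds the true generative
    probability at 0.5 — the ceiling for any trained classifier."""
    if "probs" not in truth:
        raise ValueError("truth dict lacks 'probs'")
    pred = (np.asarray(truth["probs"]) > 0.5).astype(int)
    return float(np.mean(pred == np.asarray(labels).astype(int)))


def write_cohort(
    ranges: list[ReferenceRange],
    records: list[PatientRecord],
    truth: dict,
    outdir: str,
) -> None:
    """Write ranges.csv, patients.csv and truth.json to a directory."""
    import os

    import pandas as pd

    from .kg import write_ranges

    os.makedirs(outdir, exist_ok=True)
    write_ranges(ranges, os.path.join(outdir, "ranges.csv"))
    order = [r.indicator for r in ranges]
    rows = []
    for rec in records:
        row = {ind: rec.values.get(ind) for ind in order}
        row["label"] = rec.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "patients.csv"), index=False)
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as f:
        json.dump(
            {
                "severities": truth["severities"].tolist(),
                "probs": truth["probs"].tolist(),
                "latent": truth["latent"].tolist(),
            },
            f,
        )
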