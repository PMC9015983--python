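"""Peripersonal-space boundary localization from normalized RTs.

For one Light Location, each pair of adjacent distances (D1-D2, D2-D3,
D3-D4, D4-D5) is tested with an indicator-selection model: the normalized
RTs of the two distances get a difference term whose Bernoulli inclusion
proportion quantifies the evidence that they differ.  The boundary is
declared at the adjacent pair with the largest inclusion proportion above
the positive-evidence threshold (0.75); near-equal top contrasts are
flagged as ties and resolved toward the pair nearer the body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model_core import ModelSpec
from .selection import classify_evidence, run_ivs
from .synthetic_data import DISTANCE_CM

__all__ = ["ContrastResult", "BoundaryEstimate", "consecutive_contrasts", "estimate_boundaries"]


@dataclass(frozen=True)
class ContrastResult:
    """Inclusion evidence for one adjacent-distance contrast."""

    pair: tuple[str, str]
    pair_cm: tuple[float, float]
    inclusion: float
    category: str


@dataclass
class BoundaryEstimate:
    """Ordered contrasts and the declared boundary for one light level."""

    light: str
    contrasts: list[ContrastResult]
    boundary: tuple[float, float] | None
    boundary_pair: tuple[str, str] | None
    tie: bool

    def to_dict(self) -> dict:
        return {
            "light": self.light,
            "contrasts": [
                {
                    "pair": list(c.pair),
                    "pair_cm": list(c.pair_cm),
                    "inclusion": c.inclusion,
                    "category": c.category,
                }
                for c in self.contrasts
            ],
            "boundary_cm": list(self.boundary) if self.boundary else None,
            "boundary_pair": list(self.boundary_pair) if self.boundary_pair else None,
            "tie": self.tie,
        }


def consecutive_contrasts(
    normalized: pd.DataFrame,
    light: str,
    distances: Sequence[str] = ("D1", "D2", "D3", "D4", "D5"),
    distance_cm: dict | None = None,
    threshold: float = 0.75,
    tie_tol: float = 0.05,
    chains: int = 2,
    iterations: int = 800,
    warmup: int = 400,
    seed: int = 0,
    indicator_prior: float = 0.5,
    prior_scale: float = 50.0,
) -> BoundaryEstimate:
    """Contrast each distance against the next within one light level.

    ``normalized`` is the per-participant normalized cell table
    (columns participant, distance, light_location, tactile_location,
    norm_rt).  Each adjacent pair is fitted as its own two-level model
    (difference term under indicator selection, random intercept by
    participant); tactile locations enter as replicate rows.
    """
    distance_cm = distance_cm or DISTANCE_CM
    sub = normalized[normalized["light_location"] == light]
    present = set(sub["distance"].unique())
    missing = [d for d in distances if d not in present]
    if missing:
        raise ValueError(f"light {light!r}: missing distance levels {missing}")

    spec = ModelSpec(
        response="norm_rt",
        fixed_terms=("distance",),
        random_terms=("intercept",),
        prior_scale=prior_scale,
    )
    contrasts: list[ContrastResult] = []
    for i, (d1, d2) in enumerate(zip(distances, distances[1:])):
        pair_data = sub[sub["distance"].isin([d1, d2])].reset_index(drop=True)
        res = run_ivs(
            pair_data,
            spec,
            indicator_prior=indicator_prior,
            indicator_terms=["distance"],
            chains=chains,
            iterations=iterations,
            warmup=warmup,
            seed=(seed * 37 + i) % 2**31,
        )
        p = res.inclusion["distance"]
        contrasts.append(
            ContrastResult(
                pair=(d1, d2),
                pair_cm=(float(distance_cm[d1]), float(distance_cm[d2])),
                inclusion=p,
                category=classify_evidence(p),
            )
        )

    incl = [c.inclusion for c in contrasts]
    top = max(incl)
    # tie: runner-up within tolerance of the top contrast
    near_top = [j for j, v in enumerate(incl) if top - v <= tie_tol]
    tie = len(near_top) > 1
    best = min(near_top)  # ties break toward the pair nearer the body
    declared = contrasts[best] if contrasts[best].inclusion > threshold else None
    return BoundaryEstimate(
        light=light,
        contrasts=contrasts,
        boundary=declared.pair_cm if declared else None,
        boundary_pair=declared.pair if declared else None,
        tie=tie,
    )


def estimate_boundaries(
    normalized: pd.DataFrame,
    lights: Sequence[str] | None = None,
    **kwargs,
) -> dict[str, BoundaryEstimate]:
    """Boundary estimate for every light level present in the table."""
    lights = list(lights) if lights is not None else sorted(normalized["light_location"].unique())
    seed = kwargs.pop("seed", 0)
    return {
        light: consecutive_contrasts(normalized, light, seed=seed + k, **kwargs)
        for k, light in enumerate(lights)
    }
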