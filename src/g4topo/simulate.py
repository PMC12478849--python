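"""Synthetic foldability datasets with the statistical structure the
analysis pipeline assumes.

Each conformation of the grid folds with a probability that is logistic
in additive log-odds effects: a base propensity, a penalty per
long-distance (LD) propeller that relaxes linearly with the loop's
length (vanishing at 5 nt), a capped per-nucleotide loop-length benefit,
and a hard penalty for geometrically disallowed loops (diagonal < 3 nt,
lateral < 2 nt).  The latent fold outcome may be flipped by label noise
(standing in for stochasticity of the folding trajectories), and an RMSD
to the core reference is then emitted from a class-conditional truncated
normal -- tight around a small value for folded cores, broad around a
larger value for misfolded ones -- so that percentile thresholding can
recover the outcome.

This emulates the *shape* of simulation-derived foldability data (LD
penalties, length relief, threshold-separable RMSD classes), not any
particular force field or trajectory; conclusions from it are about the
pipeline, not about real G-quadruplexes.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .geometry import classify_propellers_rule
from .topology import (
    Conformation,
    Helicity,
    LoopKind,
    conformations_to_frame,
    enumerate_conformations,
)

__all__ = [
    "EmissionParams",
    "GenerativeParams",
    "fold_log_odds",
    "fold_probability",
    "generate_records",
    "generate_folded_rmsd_trace",
    "folded_rmsd_quantile",
]


@dataclass(frozen=True)
class EmissionParams:
    """Truncated-normal RMSD emission (nm), lower bound 0."""

    mean_nm: float
    sd_nm: float

    def __post_init__(self) -> None:
        if self.mean_nm <= 0 or self.sd_nm < 0:
            raise ValueError(f"invalid emission parameters: {self}")

    def quantile(self, q: float) -> float:
        """Analytic quantile of the truncated normal (q in (0, 1))."""
        a = (0.0 - self.mean_nm) / self.sd_nm
        return float(
            truncnorm.ppf(q, a, np.inf, loc=self.mean_nm, scale=self.sd_nm)
        )

    def pdf(self, x: float) -> float:
        a = (0.0 - self.mean_nm) / self.sd_nm
        return float(truncnorm.pdf(x, a, np.inf, loc=self.mean_nm, scale=self.sd_nm))


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the synthetic foldability model.

    Log-odds effects (defaults chosen once to put the generated landscape
    in the qualitative regime of simulation-derived foldability maps:
    an all-SD-propeller topology folds almost always, an all-LD topology
    almost never, 1-nt LD loops are hopeless and the LD penalty fades by
    5 nt):

    base_log_odds
        Fold log-odds of an unpenalized conformation with 1-nt loops.
    ld_penalty
        Log-odds penalty of a 1-nt long-distance propeller; scaled by
        ``max(0, (ld_floor_nt - L)) / (ld_floor_nt - 1)`` so it shrinks
        linearly with loop length L and vanishes at ``ld_floor_nt``.
    length_benefit_per_nt
        Log-odds gain per loop nucleotide above 1, capped at
        ``length_benefit_cap_nt`` per loop.
    hard_violation_penalty
        Log-odds penalty per loop violating the survey minima
        (diagonal < 3 nt, lateral < 2 nt).
    label_noise
        Probability that the emitted fold outcome flips relative to the
        latent Bernoulli draw.
    """

    base_log_odds: float = 2.5
    ld_penalty: float = 7.0
    ld_floor_nt: int = 5
    length_benefit_per_nt: float = 0.3
    length_benefit_cap_nt: int = 4
    hard_violation_penalty: float = 9.0
    min_lateral_nt: int = 2
    min_diagonal_nt: int = 3
    label_noise: float = 0.02
    folded_emission: EmissionParams = field(
        default_factory=lambda: EmissionParams(mean_nm=0.06, sd_nm=0.015)
    )
    misfolded_emission: EmissionParams = field(
        default_factory=lambda: EmissionParams(mean_nm=0.20, sd_nm=0.05)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise <= 1:
            raise ValueError(f"label_noise must be in [0, 1]: {self.label_noise}")
        if self.folded_emission.mean_nm >= self.misfolded_emission.mean_nm:
            raise ValueError(
                "folded emission mean must be below the misfolded mean"
            )
        if self.ld_floor_nt < 2:
            raise ValueError("ld_floor_nt must be >= 2")

    def to_json(self) -> str:
        import json

        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GenerativeParams":
        import json

        d = json.loads(text)
        d["folded_emission"] = EmissionParams(**d["folded_emission"])
        d["misfolded_emission"] = EmissionParams(**d["misfolded_emission"])
        return cls(**d)


def fold_log_odds(conformation: Conformation, params: GenerativeParams) -> float:
    """Additive log-odds of folding for one conformation."""
    eta = params.base_log_odds
    labels = classify_propellers_rule(conformation.topology, conformation.helicity)
    for lt, length, label in zip(
        conformation.topology.loops, conformation.loop_lengths, labels
    ):
        eta += params.length_benefit_per_nt * (
            min(length, params.length_benefit_cap_nt) - 1
        )
        if label == "LD":
            relief = max(0, params.ld_floor_nt - length) / (params.ld_floor_nt - 1)
            eta -= params.ld_penalty * relief
        if lt.kind is LoopKind.DIAGONAL and length < params.min_diagonal_nt:
            eta -= params.hard_violation_penalty
        if lt.kind is LoopKind.LATERAL and length < params.min_lateral_nt:
            eta -= params.hard_violation_penalty
    return float(eta)


def fold_probability(conformation: Conformation, params: GenerativeParams) -> float:
    return float(expit(fold_log_odds(conformation, params)))


def _record_rng(seed: int, conformation_id: str, salt: int = 0) -> np.random.Generator:
    """Independent per-conformation stream derived from the global seed
    by hashing the conformation id (stable across runs and subsets)."""
    digest = zlib.crc32(conformation_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, digest, salt]))


def _draw_truncnorm(rng: np.random.Generator, em: EmissionParams, n: int = 1) -> np.ndarray:
    """Exact truncated-normal (lower bound 0) draws by rejection."""
    if em.sd_nm == 0:
        return np.full(n, em.mean_nm)
    out = rng.normal(em.mean_nm, em.sd_nm, size=n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(em.mean_nm, em.sd_nm, size=int(bad.sum()))
        bad = out < 0
    return out


def generate_records(
    grid: Iterable[Conformation],
    params: GenerativeParams = GenerativeParams(),
) -> pd.DataFrame:
    """Per-conformation foldability records with latent true labels.

    For each conformation the latent label is Bernoulli(fold
    probability); the emitted outcome flips with probability
    ``label_noise``; the RMSD is drawn from the outcome's emission.
    Columns: grid schema + ``fold_prob``, ``true_foldable`` (latent) and
    ``rmsd_nm``.  Fully reproducible given ``params.seed``, including on
    grid subsets (per-conformation streams).
    """
    grid = list(grid)
    frame = conformations_to_frame(grid)
    probs = np.empty(len(grid))
    latent = np.empty(len(grid), dtype=bool)
    rmsd = np.empty(len(grid))
    for i, conf in enumerate(grid):
        p = fold_probability(conf, params)
        rng = _record_rng(params.seed, conf.conformation_id)
        y = rng.random() < p
        outcome = y ^ (rng.random() < params.label_noise)
        em = params.folded_emission if outcome else params.misfolded_emission
        probs[i] = p
        latent[i] = y
        rmsd[i] = _draw_truncnorm(rng, em, 1)[0]
    frame["fold_prob"] = probs
    frame["true_foldable"] = latent
    frame["rmsd_nm"] = rmsd
    return frame


def generate_folded_rmsd_trace(
    class_key: str,
    n: int,
    params: GenerativeParams = GenerativeParams(),
) -> np.ndarray:
    """I.i.d. folded-state RMSD draws for one core class (e.g.
    ``"3T-RH"``), emulating a core-fluctuation trace used to set the
    percentile threshold."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _record_rng(params.seed, f"rmsd-trace|{class_key}", salt=1)
    return _draw_truncnorm(rng, params.folded_emission, n)


def folded_rmsd_quantile(params: GenerativeParams, q: float) -> float:
    """Analytic quantile of the folded RMSD emission (oracle for the
    empirical percentile threshold)."""
    return params.folded_emission.quantile(q)
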