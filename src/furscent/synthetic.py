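"""Synthetic chemical-fingerprint datasets with controllable variance structure.

The generator emulates the structure of skin-swab GC-MS peak tables from a
colonially breeding pinniped: mother-offspring pairs (occasionally trios
with twins) nested within breeding colonies, plus pup-only colonies, with
group signal present at the colony, family and individual level in both
which compounds are detected and how abundant they are.

Generative model (all effects on the natural-log scale):

    b_m       ~ Normal(base_log_mean, base_log_sd)        per compound m
    delta_cm  ~ Normal(0, sigma_colony)                   per colony x compound
    gamma_fm  ~ Normal(0, sigma_family)                   per family x compound
    eps_im    ~ Normal(0, sigma_individual)               per individual x compound
    L_im      = b_m + delta_c(i)m + gamma_f(i)m + eps_im
    detected  ~ Bernoulli( logistic( detection_slope * (L_im - tau) ) )
    abundance = exp(L_im) if detected else 0

The detection threshold tau is solved numerically once per dataset so that
the expected number of detected compounds per sample equals ``mean_detected``
(default 42, the typical per-sample chemical richness of such fingerprints).
Coupling detection to the latent abundance makes presence/absence and
abundance carry correlated group signal, as in real sparse fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import AbundanceMatrix, FingerprintError, SampleMetadata, ValidatedDataset

_QUAD_NODES, _QUAD_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_QUAD_WEIGHTS = _QUAD_WEIGHTS / _QUAD_WEIGHTS.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic fingerprint generator.

    ``families_per_colony`` and ``pup_only`` accept either a scalar (applied
    to every colony) or one value per colony.  ``n_twins`` forces an exact
    number of twin trios (assigned to the first mother-pup families);
    when None, each family is a trio independently with ``twin_probability``.
    """

    n_colonies: int = 2
    families_per_colony: int | Sequence[int] = 25
    pup_only: bool | Sequence[bool] = False
    twin_probability: float = 0.02
    n_twins: int | None = None
    pool_size: int = 200
    mean_detected: float = 42.0
    sigma_colony: float = 0.4
    sigma_family: float = 0.6
    sigma_individual: float = 1.0
    detection_slope: float = 1.5
    base_log_mean: float = 2.0
    base_log_sd: float = 1.0
    colony_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise FingerprintError("need at least one colony")
        for s in (self.sigma_colony, self.sigma_family, self.sigma_individual):
            if s < 0:
                raise FingerprintError("sd parameters must be nonnegative")
        if not 0 <= self.twin_probability <= 1:
            raise FingerprintError("twin_probability must be in [0, 1]")
        if self.mean_detected > self.pool_size:
            raise FingerprintError(
                f"mean_detected ({self.mean_detected}) exceeds pool_size ({self.pool_size})"
            )

    def _per_colony(self, value, caster):
        if np.isscalar(value):
            return [caster(value)] * self.n_colonies
        out = [caster(v) for v in value]
        if len(out) != self.n_colonies:
            raise FingerprintError("per-colony list length != n_colonies")
        return out

    @property
    def colony_labels(self) -> list[str]:
        if self.colony_names is not None:
            if len(self.colony_names) != self.n_colonies:
                raise FingerprintError("colony_names length != n_colonies")
            return list(self.colony_names)
        return [f"C{i + 1}" for i in range(self.n_colonies)]


def _solve_tau(b: np.ndarray, sd_effects: float, slope: float,
               target: float) -> float:
    """Detection threshold giving an expected ``target`` detected compounds.

    Expectation of logistic(slope * (L - tau)) over L ~ Normal(b_m, sd_effects)
    via Gauss-Hermite quadrature, summed over compounds, solved for tau.
    """
    if sd_effects > 0:
        L = b[:, None] + sd_effects * _QUAD_NODES[None, :]

        def expected(tau):
            return (expit(slope * (L - tau)) @ _QUAD_WEIGHTS).sum() - target
    else:
        def expected(tau):
            return expit(slope * (b - tau)).sum() - target

    lo = b.min() - 10 * (sd_effects + 1 / slope + 1)
    hi = b.max() + 10 * (sd_effects + 1 / slope + 1)
    return brentq(expected, lo, hi, xtol=1e-10)


def _design(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sampling design: one row per individual with colony/age/family labels."""
    fams = config._per_colony(config.families_per_colony, int)
    pup_only = config._per_colony(config.pup_only, bool)
    rows = []
    pair_fams = []  # mother-pup families eligible for twins, in order
    for c_idx, colony in enumerate(config.colony_labels):
        for f in range(fams[c_idx]):
            fam_id = f"{colony}_F{f + 1:02d}"
            if pup_only[c_idx]:
                rows.append((f"{fam_id}_P1", colony, "pup", fam_id))
            else:
                rows.append((f"{fam_id}_M", colony, "mother", fam_id))
                rows.append((f"{fam_id}_P1", colony, "pup", fam_id))
                pair_fams.append(fam_id)
    if config.n_twins is not None:
        if config.n_twins > len(pair_fams):
            raise FingerprintError("more twins requested than mother-pup families")
        twin_fams = set(pair_fams[:config.n_twins])
    else:
        twin_fams = {f for f in pair_fams if rng.random() < config.twin_probability}
    for fam_id in sorted(twin_fams):
        colony = fam_id.split("_F")[0]
        rows.append((f"{fam_id}_P2", colony, "pup", fam_id))
    df = pd.DataFrame(rows, columns=["sample_id", "colony", "age_class", "family_id"])
    return df.sort_values(["colony", "family_id", "sample_id"],
                          key=lambda s: s.map(str)).reset_index(drop=True)


def generate_dataset(config: SyntheticConfig) -> ValidatedDataset:
    """Draw one synthetic fingerprint dataset, fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    design = _design(config, rng)
    n, M = len(design), config.pool_size

    b = rng.normal(config.base_log_mean, config.base_log_sd, M)
    colonies = design["colony"].to_numpy()
    families = design["family_id"].to_numpy()
    colony_levels = list(dict.fromkeys(colonies))
    family_levels = list(dict.fromkeys(families))
    delta = rng.normal(0, config.sigma_colony, (len(colony_levels), M))
    gamma = rng.normal(0, config.sigma_family, (len(family_levels), M))
    eps = rng.normal(0, config.sigma_individual, (n, M))

    c_idx = np.array([colony_levels.index(c) for c in colonies])
    f_idx = np.array([family_levels.index(f) for f in families])
    L = b[None, :] + delta[c_idx] + gamma[f_idx] + eps

    sd_effects = float(np.sqrt(config.sigma_colony ** 2 + config.sigma_family ** 2
                               + config.sigma_individual ** 2))
    tau = _solve_tau(b, sd_effects, config.detection_slope, config.mean_detected)
    detected = rng.random((n, M)) < expit(config.detection_slope * (L - tau))
    # a fingerprint with no peaks at all is not a usable sample: force the
    # strongest latent compound to be detected in that (rare) case
    empty = ~detected.any(axis=1)
    if empty.any():
        detected[np.nonzero(empty)[0], L[empty].argmax(axis=1)] = True

    values = np.where(detected, np.exp(L), 0.0)
    rts = np.sort(rng.uniform(5.0, 45.0, M))
    compound_ids = [f"{rt:.3f}" for rt in rts]
    # retention times are labels only; perturb duplicates to keep them unique
    seen: set[str] = set()
    for i, cid in enumerate(compound_ids):
        while cid in seen:
            cid = cid + "0"
        seen.add(cid)
        compound_ids[i] = cid

    matrix = AbundanceMatrix(design["sample_id"].tolist(), compound_ids, values, "raw")
    return ValidatedDataset(matrix, SampleMetadata(design))


def study_design_config(which: str, seed: int = 0) -> SyntheticConfig:
    """Presets mirroring the three study designs.

    ``replication``: 50 mother-offspring pairs (one twin trio) from two
    colonies, SSB and FWB -> 101 samples.  ``original``: 41 pairs from the
    same two colonies -> 82 samples.  ``six_colony``: pups only from six
    colonies (25 + 25 + 4 x 15) -> 110 samples.
    """
    if which == "replication":
        return SyntheticConfig(n_colonies=2, families_per_colony=25,
                               colony_names=("SSB", "FWB"), n_twins=1, seed=seed)
    if which == "original":
        return SyntheticConfig(n_colonies=2, families_per_colony=(21, 20),
                               colony_names=("SSB", "FWB"), n_twins=0, seed=seed)
    if which == "six_colony":
        return SyntheticConfig(
            n_colonies=6, families_per_colony=(25, 25, 15, 15, 15, 15),
            pup_only=True, n_twins=0,
            colony_names=("SSB", "FWB", "Johnson Cove", "Main Bay",
                          "Landing Beach", "Natural Arch"),
            seed=seed)
    raise FingerprintError(f"unknown preset {which!r}; use replication, original "
                           "or six_colony")
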