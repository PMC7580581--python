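"""Bootstrap standardization of PERMANOVA effect sizes (R-squared).

Permutation p-values are not comparable between studies of different sample
size, so effect sizes are standardized instead: mother-offspring families
are resampled with replacement (a fixed number per colony, default 15 pairs
from each of two colonies, i.e. about 60 individuals per replicate), the
PERMANOVA is refitted on each resampled dataset, and the per-term R-squared
values are collected.  Each distribution is summarized by its maximum-density
estimate (the mode of a Gaussian KDE), quartiles and 2.5/97.5% quantiles.

The resampling unit is the family, not the individual: the family term of
the model requires intact mother-offspring units, and a family drawn more
than once enters each time under a fresh label so the family degrees of
freedom stay at (#families - #colonies) in every replicate.  Twin trios are
carried whole, so replicate sample counts can slightly exceed the nominal
2 x 2 x pairs_per_colony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .dissimilarity import bray_curtis
from .io import AbundanceMatrix, FingerprintError, SampleMetadata, ValidatedDataset
from .permanova import ModelSpec, permanova

_KDE_GRID = 512


@dataclass(frozen=True)
class BootstrapSpec:
    """Settings of the family-level bootstrap."""

    pairs_per_colony: int = 15
    replicates: int = 5_000
    focal_terms: tuple[str, ...] | None = None  # None = every model term
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pairs_per_colony < 2:
            raise FingerprintError("pairs_per_colony must be >= 2")
        if self.replicates < 1:
            raise FingerprintError("replicates must be >= 1")


@dataclass(frozen=True)
class BootstrapDistribution:
    """Replicate R-squared values per focal term, plus full-data values."""

    replicates: pd.DataFrame           # one column per focal term, B rows
    full_data_r2: dict[str, float]

    @property
    def terms(self) -> list[str]:
        return list(self.replicates.columns)

    def summary(self) -> pd.DataFrame:
        return summarize_bootstrap(self)


def max_density_estimate(samples: np.ndarray) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) over the sample values.

    Density is evaluated on a 512-point grid spanning [min - 3h, max + 3h];
    ties break toward the smaller grid value.  If all values are identical
    that value is returned directly.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise FingerprintError("max_density_estimate needs at least 10 samples")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, _KDE_GRID)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])  # argmax returns the first (smallest) tie


def _resample(dataset: ValidatedDataset, spec: BootstrapSpec,
              rng: np.random.Generator) -> ValidatedDataset:
    meta = dataset.metadata.table
    values = dataset.matrix.values
    rows: list[int] = []
    new_meta: list[dict] = []
    copy = 0
    for colony, fam_ids in _families_by_colony(meta).items():
        draws = rng.choice(len(fam_ids), size=spec.pairs_per_colony, replace=True)
        for d in draws:
            copy += 1
            fam = fam_ids[d]
            members = np.nonzero((meta["family_id"] == fam).to_numpy())[0]
            for i in members:
                rows.append(i)
                r = meta.iloc[i]
                new_meta.append({"sample_id": f"{r['sample_id']}~{copy}",
                                 "colony": r["colony"],
                                 "age_class": r.get("age_class"),
                                 "family_id": f"{fam}~{copy}"})
    matrix = AbundanceMatrix([m["sample_id"] for m in new_meta],
                             dataset.matrix.compound_ids,
                             values[rows], dataset.matrix.unit_state)
    return ValidatedDataset(matrix, SampleMetadata(pd.DataFrame(new_meta)))


def _families_by_colony(meta: pd.DataFrame) -> dict[str, list[str]]:
    if "family_id" not in meta.columns or meta["family_id"].isna().any():
        raise FingerprintError("bootstrap requires family_id for every sample")
    out: dict[str, list[str]] = {}
    for colony, grp in meta.groupby("colony", sort=True):
        fams = sorted(grp["family_id"].unique())
        if len(fams) < 2:
            raise FingerprintError(f"colony {colony!r} has fewer than 2 families")
        out[colony] = fams
    return out


def bootstrap_effect_sizes(dataset: ValidatedDataset, model: ModelSpec,
                           spec: BootstrapSpec) -> BootstrapDistribution:
    """Family-level bootstrap distribution of per-term PERMANOVA R-squared.

    ``dataset`` must be preprocessed (log-transformed relative abundances).
    Per replicate, ``pairs_per_colony`` families are drawn with replacement
    independently within each colony; Bray-Curtis distances are recomputed on
    the resampled rows and the model refitted with permutations disabled
    (only R-squared is consumed).  The full-data R-squared is computed once
    on the unresampled dataset.
    """
    if dataset.matrix.unit_state != "log_relative":
        raise FingerprintError("bootstrap_effect_sizes expects a preprocessed "
                               f"(log_relative) dataset, got {dataset.matrix.unit_state!r}")
    colonies = pd.unique(dataset.metadata.table["colony"])
    if len(colonies) != 2:
        raise FingerprintError(f"bootstrap expects exactly 2 colonies, got {len(colonies)}")
    _families_by_colony(dataset.metadata.table)  # validates family structure

    focal = list(spec.focal_terms) if spec.focal_terms else [t.name for t in model.terms]
    quiet = ModelSpec(model.terms, permutations=0, seed=model.seed)

    full = permanova(bray_curtis(dataset.matrix), dataset.metadata, quiet)
    full_r2 = {t: full.r2(t) for t in focal}

    rng = np.random.default_rng(spec.seed)
    records = np.empty((spec.replicates, len(focal)))
    for b in range(spec.replicates):
        boot = _resample(dataset, spec, rng)
        tab = permanova(bray_curtis(boot.matrix), boot.metadata, quiet)
        records[b] = [tab.r2(t) for t in focal]
    reps = pd.DataFrame(records, columns=focal)
    if ((reps.values < -1e-12) | (reps.values > 1 + 1e-12)).any():
        raise FingerprintError("bootstrap produced an R2 outside [0, 1]")
    return BootstrapDistribution(replicates=reps.clip(0.0, 1.0), full_data_r2=full_r2)


def summarize_bootstrap(dist: BootstrapDistribution) -> pd.DataFrame:
    """Boxplot-style summary per focal term.

    Median, quartiles, 1.5 x IQR whisker bounds (clipped to the observed
    range), 2.5/97.5% quantiles (linear interpolation), the maximum-density
    estimate and the full-data R-squared.
    """
    rows = []
    for term in dist.terms:
        x = dist.replicates[term].to_numpy()
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        rows.append({
            "term": term,
            "median": med, "q1": q1, "q3": q3,
            "whisker_low": lo, "whisker_high": hi,
            "q025": np.quantile(x, 0.025), "q975": np.quantile(x, 0.975),
            "max_density": max_density_estimate(x),
            "full_data_r2": dist.full_data_r2[term],
        })
    return pd.DataFrame(rows)
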