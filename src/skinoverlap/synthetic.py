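"""Synthetic ISSA-like skin-colour datasets.

The real archive cannot be bundled, so every downstream stage is
exercised on generated data with a known truth.  The generative model is
deliberately simple: each subject draws a trivariate Gaussian
(L*, a*, b*) deviate from their group's location/spread, and each
measurement adds an optional per-site offset, an optional gender
offset, and small within-subject Gaussian noise.  Group locations and
marginal spreads of the default ``issa_like`` preset are the published
per-group CIELAB means and standard deviations of the eight-group
archive; the covariance is diagonal by default (only marginal moments
are published), with an optional L*–b* coupling to imitate the
banana-shaped lightness–chroma distribution of real skin.

What this emulates: group separations, marginal spreads, per-group
sample sizes, gender labels, ten body sites per subject.  What it does
not: spectral structure, site-specific colour shifts of real anatomy,
age effects, and the true within- vs between-subject variance split of
the archive (unpublished; the default split puts nearly all variance
between subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ANALYSIS_SITES, GROUPS, SkinDataset

__all__ = [
    "GroupModel",
    "ScenarioConfig",
    "generate_dataset",
    "preset_scenarios",
    "two_group_partial",
    "ISSA_LIKE_MOMENTS",
]

#: Published per-group CIELAB mean and SD of (L*, a*, b*) for the eight
#: archive groups, and per-group measurement counts (spectra).
ISSA_LIKE_MOMENTS: dict[str, dict] = {
    "CA": {"mean": (61.2, 11.0, 14.7), "sd": (5.4, 3.9, 2.7), "n_spectra": 2376, "female_fraction": 274 / 352},
    "CN": {"mean": (59.8, 10.1, 16.7), "sd": (4.3, 2.9, 2.4), "n_spectra": 2736, "female_fraction": 177 / 370},
    "JP": {"mean": (63.5, 9.8, 17.0), "sd": (4.2, 2.7, 2.6), "n_spectra": 944, "female_fraction": 67 / 118},
    "SA": {"mean": (52.7, 10.4, 17.9), "sd": (6.4, 2.5, 2.3), "n_spectra": 1289, "female_fraction": 92 / 157},
    "AF": {"mean": (39.6, 10.2, 14.4), "sd": (6.7, 2.0, 4.3), "n_spectra": 929, "female_fraction": 85 / 145},
    "IQ": {"mean": (57.3, 10.2, 15.8), "sd": (5.5, 3.2, 2.4), "n_spectra": 1183, "female_fraction": 77 / 149},
    "TH": {"mean": (56.4, 10.0, 19.0), "sd": (5.6, 2.4, 2.6), "n_spectra": 4112, "female_fraction": 494 / 708},
    "AB": {"mean": (60.2, 10.9, 17.9), "sd": (6.5, 3.0, 2.5), "n_spectra": 963, "female_fraction": 87 / 107},
}


@dataclass(frozen=True)
class GroupModel:
    """Generative model for one group's measurements."""

    group: str
    n_subjects: int
    mean: tuple[float, float, float]
    covariance: np.ndarray
    sites_per_subject: int = 10
    site_offsets: Mapping[str, Sequence[float]] | None = None
    gender_offset: tuple[float, float, float] | None = None  # added for males
    female_fraction: float = 0.5
    within_subject_noise: float = 0.5  # RMS ΔE*ab of measurement noise

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance must be a symmetric 3×3 matrix")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-8:
            raise ValueError("covariance must be positive semi-definite")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be ≥ 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named set of group models plus the seed that reproduces the draw.

    ``share_draws`` replicates one common draw across all groups,
    translated to each group's mean: the groups then differ *only* by
    location, which makes full overlap exact in the ``identical``
    scenario and makes overlap a clean monotone function of mean
    separation in ``two_group_partial`` sweeps (no re-drawing noise).
    Group models should share spread settings for this to be meaningful.
    """

    groups: tuple[GroupModel, ...]
    seed: int
    label: str = "custom"
    share_draws: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        codes = [g.group for g in self.groups]
        if len(set(codes)) != len(codes):
            raise ValueError("group codes must be unique")


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    # eigendecomposition instead of Cholesky so singular (zero-spread)
    # covariances are accepted
    vals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_dataset(config: ScenarioConfig) -> SkinDataset:
    """Draw a full dataset; identical config + seed ⇒ identical output."""
    rng = np.random.default_rng(config.seed)
    frames = []
    if config.share_draws:
        first = generate_dataset(
            ScenarioConfig((config.groups[0],), config.seed, config.label)
        ).frame
        base_mean = np.asarray(config.groups[0].mean)
        for gm in config.groups:
            clone = first.copy()
            clone["group"] = gm.group
            clone["subject_id"] = clone["subject_id"].str.replace(
                config.groups[0].group, gm.group, n=1
            )
            clone[["L", "a", "b"]] += np.asarray(gm.mean) - base_mean
            frames.append(clone)
        frame = pd.concat(frames, ignore_index=True)
        return SkinDataset(frame, provenance={"generator": config.label, "seed": config.seed})
    for gm in config.groups:
        factor = _psd_factor(gm.covariance)
        sites = list(ANALYSIS_SITES)[: gm.sites_per_subject]
        if gm.sites_per_subject > len(ANALYSIS_SITES):
            raise ValueError("sites_per_subject exceeds the site vocabulary")
        n_sub, n_site = gm.n_subjects, len(sites)
        subj_dev = rng.standard_normal((n_sub, 3)) @ factor.T + np.asarray(gm.mean)
        genders = np.where(rng.random(n_sub) < gm.female_fraction, "female", "male")
        if gm.gender_offset is not None:
            subj_dev = subj_dev + np.where(
                (genders == "male")[:, None], np.asarray(gm.gender_offset), 0.0
            )
        noise_sd = gm.within_subject_noise / np.sqrt(3.0)
        meas = np.repeat(subj_dev, n_site, axis=0)
        if gm.site_offsets:
            offs = np.array([gm.site_offsets.get(s, (0.0, 0.0, 0.0)) for s in sites])
            meas = meas + np.tile(offs, (n_sub, 1))
        meas = meas + rng.standard_normal(meas.shape) * noise_sd
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(
                        [f"{gm.group}{i + 1:04d}" for i in range(n_sub)], n_site
                    ),
                    "group": gm.group,
                    "gender": np.repeat(genders, n_site),
                    "age": np.nan,
                    "body_site": np.tile(sites, n_sub),
                    "L": meas[:, 0],
                    "a": meas[:, 1],
                    "b": meas[:, 2],
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return SkinDataset(
        frame,
        provenance={"generator": config.label, "seed": config.seed},
    )


def _issa_like_groups(n_subjects: int | None = None,
                      lab_coupling: float = 0.0) -> tuple[GroupModel, ...]:
    models = []
    for code in GROUPS:
        spec = ISSA_LIKE_MOMENTS[code]
        sd = np.asarray(spec["sd"])
        cov = np.diag(sd ** 2)
        if lab_coupling:
            # positive L*–b* coupling (banana-shaped L*C* cloud)
            cov[0, 2] = cov[2, 0] = lab_coupling * sd[0] * sd[2]
        n_sub = n_subjects if n_subjects is not None else max(1, round(spec["n_spectra"] / 10))
        models.append(
            GroupModel(
                group=code,
                n_subjects=n_sub,
                mean=tuple(spec["mean"]),
                covariance=cov,
                female_fraction=spec["female_fraction"],
            )
        )
    return tuple(models)


def preset_scenarios(seed: int = 42, n_subjects: int | None = None) -> dict[str, ScenarioConfig]:
    """Named scenario presets.

    issa_like
        Eight groups at the published archive locations/spreads; subject
        counts default to one tenth of each group's measurement count so
        generated sample sizes match the archive's.
    identical
        Eight groups sharing one common draw (every group holds the
        same samples, so overlap is exactly 100% in every cell).
    disjoint
        Eight tight groups spaced 30 L* units apart (no overlap).
    two_group_partial
        Two groups whose mean separation is configurable via
        :func:`two_group_partial`; the preset uses separation 6.
    """
    common = GroupModel(
        group="CA", n_subjects=150, mean=(55.0, 10.0, 16.0),
        covariance=np.diag([25.0, 9.0, 9.0]),
    )
    identical = tuple(replace(common, group=g) for g in GROUPS)
    disjoint = tuple(
        GroupModel(
            group=g, n_subjects=150, mean=(30.0 * i, 10.0, 16.0),
            covariance=np.diag([1.0, 1.0, 1.0]),
        )
        for i, g in enumerate(GROUPS)
    )
    return {
        "issa_like": ScenarioConfig(_issa_like_groups(n_subjects), seed, "issa_like"),
        "identical": ScenarioConfig(identical, seed, "identical", share_draws=True),
        "disjoint": ScenarioConfig(disjoint, seed, "disjoint"),
        "two_group_partial": two_group_partial(6.0, seed=seed),
    }


def two_group_partial(
    separation: float,
    n_subjects: int = 150,
    seed: int = 42,
    sd: Sequence[float] = (4.5, 2.5, 2.5),
) -> ScenarioConfig:
    """Two groups whose means differ by ``separation`` L* units.

    The groups share one draw (translated), so across a separation
    sweep at fixed seed the mean separation is the *only* thing that
    changes and both overlap statistics respond monotonically to it.
    """
    cov = np.diag(np.asarray(sd, dtype=float) ** 2)
    base = (55.0, 10.0, 16.0)
    shifted = (55.0 + separation, 10.0, 16.0)
    groups = (
        GroupModel(group="CA", n_subjects=n_subjects, mean=base, covariance=cov),
        GroupModel(group="CN", n_subjects=n_subjects, mean=shifted, covariance=cov),
    )
    return ScenarioConfig(
        groups, seed, f"two_group_partial(sep={separation:g})", share_draws=True
    )
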