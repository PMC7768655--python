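"""Synthetic multimodal cohorts.

Real studies of this kind pair, for each subject, a structural connectivity
(SC) matrix from diffusion-MRI tractography with a regional BOLD time-series
matrix from resting-state fMRI, plus a binary group label.  Such data are
access-restricted, so this module generates surrogate cohorts whose essential
statistical structure is controllable:

* modular SC templates (within-module streamline-like weights drawn above
  between-module weights),
* BOLD series whose spatial covariance is a convex combination of identity
  and an SC-derived correlation matrix — stronger structural connections
  induce stronger functional coupling,
* a planted group effect that attenuates within-module functional coupling
  for the "carrier" group only.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CARRIER = "carrier"
NONCARRIER = "noncarrier"
GROUPS = (CARRIER, NONCARRIER)


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for one synthetic cohort.

    Defaults mirror a two-group resting-state study: 27 carriers vs 36
    non-carriers, 90 atlas regions, 280 time points.  ``effect_size`` scales
    the attenuation of within-module functional coupling in carriers
    (0 = null cohort, 1 = coupling fully removed).
    """

    n_carriers: int = 27
    n_noncarriers: int = 36
    n_rois: int = 90
    n_timepoints: int = 280
    n_modules: int = 6
    within_module_density: float = 0.85
    between_module_density: float = 0.08
    sc_weight_scale: float = 1.0
    coupling_strength: float = 0.6
    effect_size: float = 0.5
    noise_sd: float = 1.0
    sc_jitter_sd: float = 0.1
    ar_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_carriers", "n_noncarriers", "n_rois", "n_timepoints", "n_modules"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        if self.n_rois < 4:
            raise ParameterError("n_rois must be >= 4")
        if self.n_modules > self.n_rois:
            raise ParameterError("n_modules cannot exceed n_rois")
        for name in ("within_module_density", "between_module_density",
                     "coupling_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if self.sc_weight_scale < 0:
            raise ParameterError("sc_weight_scale must be nonnegative")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ParameterError("ar_coefficient must lie in (-1, 1)")
        if self.n_timepoints < self.n_rois:
            warnings.warn(
                "n_timepoints < n_rois: per-region regressions are "
                "underdetermined; sparse penalties are required.",
                UserWarning, stacklevel=2,
            )


@dataclass
class SubjectRecord:
    """One subject: BOLD matrix (T x M), SC matrix (M x M), group label."""

    subject_id: str
    bold: np.ndarray
    sc: np.ndarray
    group: str

    def validate(self) -> "SubjectRecord":
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}")
        sc = np.asarray(self.sc, dtype=float)
        if sc.ndim != 2 or sc.shape[0] != sc.shape[1]:
            raise ParameterError("sc must be square")
        if not np.allclose(sc, sc.T):
            raise ParameterError("sc must be symmetric")
        if np.any(sc < 0):
            raise ParameterError("sc must be nonnegative")
        if np.any(np.diag(sc) != 0):
            raise ParameterError("sc diagonal must be zero")
        bold = np.asarray(self.bold, dtype=float)
        if bold.ndim != 2 or bold.shape[1] != sc.shape[0]:
            raise ParameterError("bold must be T x M matching sc")
        if not np.all(np.isfinite(bold)):
            raise ParameterError("bold contains non-finite entries")
        return self


def module_labels(n_rois: int, n_modules: int) -> np.ndarray:
    """Balanced assignment of ROIs 0..M-1 to modules 0..n_modules-1."""
    return np.sort(np.arange(n_rois) % n_modules)


def generate_structural_network(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw a modular SC template.

    Within-module edges appear with probability ``within_module_density`` and
    carry heavy-tailed weights ``sc_weight_scale * 0.2 * exp(1.2 |Z|)`` with
    Z standard normal — streamline-count-like: a few dominant bundles and
    many moderate ones, which is what keeps the downstream penalty kernel's
    variance-based bandwidth on the scale of typical squared weights.
    Between-module edges appear with probability ``between_module_density``
    and carry weights uniform on ``sc_weight_scale * [0.02, 0.18]``, strictly
    below the within-module range, so module structure survives
    thresholding.
    """
    m = spec.n_rois
    labels = module_labels(m, spec.n_modules)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(m, k=1)
    same_u = same[iu]

    present = np.where(
        same_u,
        rng.random(same_u.size) < spec.within_module_density,
        rng.random(same_u.size) < spec.between_module_density,
    )
    within_w = 0.2 * np.exp(1.2 * np.abs(rng.standard_normal(same_u.size)))
    between_w = rng.uniform(0.02, 0.18, size=same_u.size)
    w = np.where(same_u, within_w, between_w) * spec.sc_weight_scale * present

    sc = np.zeros((m, m))
    sc[iu] = w
    sc += sc.T
    return sc


def _sc_covariance(spec: CohortSpec, sc: np.ndarray, group: str) -> np.ndarray:
    """Spatial covariance for BOLD sampling: (1-c) I + c corr(walk-sum(SC)).

    The SC-derived part is the walk-sum forward model
    ``(I - A)^{-1}`` with A = SC rescaled to spectral radius 0.8: functional
    correlation accumulates over all white-matter walks, so directly
    connected pairs correlate most strongly (stronger SC => stronger FC) and
    indirectly connected pairs acquire smaller correlations.  The inverse is
    positive definite by construction (eigenvalues of I - A are >= 0.2).

    Carriers have within-module SC entries attenuated by ``effect_size``
    before the covariance is built, so their functional coupling inside
    modules is weaker while the observed SC matrices stay identical in
    distribution across groups.
    """
    m = sc.shape[0]
    # degree-normalized adjacency: spectral radius <= 1 whatever the weight
    # scale, so a single dominant bundle cannot suppress everyone else's
    # coupling; 0.8 keeps I - A safely positive definite
    deg = sc.sum(axis=1)
    dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
    a = 0.8 * (dinv_sqrt[:, None] * sc * dinv_sqrt[None, :])
    if group == CARRIER and spec.effect_size > 0:
        labels = module_labels(m, spec.n_modules)
        within = labels[:, None] == labels[None, :]
        a = a.copy()
        a[within] *= max(0.0, 1.0 - spec.effect_size)
    # entrywise shrinkage cannot raise the spectral radius, so I - A stays PD
    b = np.linalg.inv(np.eye(m) - a)
    dinv = 1.0 / np.sqrt(np.diag(b))
    corr = dinv[:, None] * b * dinv[None, :]

    c = spec.coupling_strength
    cov = (1.0 - c) * np.eye(m) + c * corr
    # diagonal loading keeps the Cholesky factor well defined at c = 1
    return cov + 1e-6 * np.eye(m)


def generate_bold(
    spec: CohortSpec, sc: np.ndarray, group: str, rng: np.random.Generator
) -> np.ndarray:
    """Sample a T x M Gaussian BOLD matrix with SC-coupled spatial covariance.

    Rows are i.i.d. by default; ``ar_coefficient`` != 0 adds AR(1) temporal
    correlation (the downstream method uses only spatial covariance).
    """
    if group not in GROUPS:
        raise ParameterError(f"group must be one of {GROUPS}")
    cov = _sc_covariance(spec, np.asarray(sc, dtype=float), group)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:  # pragma: no cover - prevented by loading
        chol = np.linalg.cholesky(cov + 1e-9 * np.eye(cov.shape[0]))
    t, m = spec.n_timepoints, spec.n_rois
    z = rng.standard_normal((t, m))
    phi = spec.ar_coefficient
    if phi != 0.0:
        for row in range(1, t):
            z[row] = phi * z[row - 1] + np.sqrt(1.0 - phi**2) * z[row]
    return spec.noise_sd * (z @ chol.T)


def _jitter_sc(sc: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal edge jitter, kept symmetric."""
    if sd <= 0:
        return sc.copy()
    m = sc.shape[0]
    iu = np.triu_indices(m, k=1)
    factor = np.exp(rng.normal(0.0, sd, size=iu[0].size))
    out = np.zeros_like(sc)
    out[iu] = sc[iu] * factor
    out += out.T
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort: one SC template per run, per-subject jitter.

    Subject order is all carriers then all non-carriers; ids are stable
    (``carrier_00`` ...), and the random stream is split per subject so the
    cohort is reproducible as a whole and per subject.
    """
    root = np.random.SeedSequence(spec.seed)
    template_rng = np.random.default_rng(root.spawn(1)[0])
    template = generate_structural_network(spec, template_rng)

    n_total = spec.n_carriers + spec.n_noncarriers
    seeds = root.spawn(n_total + 1)[1:]
    records: list[SubjectRecord] = []
    for idx in range(n_total):
        group = CARRIER if idx < spec.n_carriers else NONCARRIER
        local = idx if group == CARRIER else idx - spec.n_carriers
        rng = np.random.default_rng(seeds[idx])
        sc = _jitter_sc(template, spec.sc_jitter_sd, rng)
        bold = generate_bold(spec, sc, group, rng)
        records.append(
            SubjectRecord(f"{group}_{local:02d}", bold, sc, group).validate()
        )
    return records


# ---------------------------------------------------------------------------
# on-disk cohort format: per-subject TSVs plus a manifest CSV


def roi_names(n_rois: int) -> list[str]:
    return [f"ROI{i:03d}" for i in range(n_rois)]


def write_cohort(records: list[SubjectRecord], outdir) -> "pd.DataFrame":
    """Write BOLD/SC TSVs and a manifest CSV; returns the manifest frame."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        names = roi_names(rec.bold.shape[1])
        bold_path = outdir / f"{rec.subject_id}_bold.tsv"
        sc_path = outdir / f"{rec.subject_id}_sc.tsv"
        pd.DataFrame(rec.bold, columns=names).to_csv(bold_path, sep="\t", index=False)
        pd.DataFrame(rec.sc, columns=names).to_csv(sc_path, sep="\t", index=False)
        rows.append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "bold_path": bold_path.name, "sc_path": sc_path.name}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_cohort(manifest_path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    records = []
    for row in manifest.itertuples(index=False):
        bold = pd.read_csv(base / row.bold_path, sep="\t").to_numpy(dtype=float)
        sc = pd.read_csv(base / row.sc_path, sep="\t").to_numpy(dtype=float)
        records.append(SubjectRecord(row.subject_id, bold, sc, row.group).validate())
    return records
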