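"""Synthetic fibroblast cohorts with realistic bioenergetic structure.

Generates raw well-level plate data for a four-group cohort (control,
sALS, PLS, C9orf72) whose per-feature marginal means/SDs and pairwise
Spearman rank correlations match a configured specification. The default
configuration encodes the observed summary statistics of a large motor
neuron disease fibroblast cohort (91 controls, 171 sALS, 34 PLS, 13
C9orf72 lines).

Construction
------------
Ground-truth line profiles are drawn from a Gaussian copula: latent
standard normals are correlated with the Pearson counterpart of the
target Spearman rho (the classical sin transform
``r = 2*sin(pi*rho_s/6)``), then pushed through the marginal inverse
CDFs — lognormal for the strictly positive assay features, normal for
the oligomycin ATP delta, whose observed mean is negative. Rank
correlations survive the monotone marginal transforms, so the Spearman
structure is imposed exactly (up to positive-semidefinite repair).

Two features are deterministic functions of others and are recomputed
after sampling so the profile identities hold exactly: spare respiratory
capacity (``ocr_max - ocr_base``) and the OCR/ECAR ratio. The spare SD is
matched to its configured value by calibrating the latent correlation
between baseline and maximal OCR through the exact lognormal covariance
formula; the ratio's moments are emergent, since its parents' correlation
is itself a rank-correlation target. Rank targets that involve the ratio
are honoured by solving for a free direct correlation through the ratio's
latent linear representation.

Well-level rendering inverts the feature-extraction pipeline: with zero
technical noise the pipeline recovers the ground-truth profile to
floating-point precision, which is the module's core oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ATP_CONDITIONS, FEATURES, FLUX_PHASES, Cohort

__all__ = [
    "MarginalSpec",
    "GroupSpec",
    "NoiseSpec",
    "SyntheticConfig",
    "SAMPLED_FEATURES",
    "DERIVED_FEATURES",
    "default_config",
    "latent_correlation",
    "nearest_psd",
    "sample_line_profiles",
    "render_plate_data",
    "generate_cohort",
]

#: Features drawn directly from the copula, in sampling order.
DERIVED_FEATURES = ("ocr_spare", "ocr_ecar_ratio")
SAMPLED_FEATURES = tuple(f for f in FEATURES if f not in DERIVED_FEATURES)


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one feature on the observed scale."""

    family: str  # "lognormal" | "normal"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown marginal family '{self.family}'")
        if self.sd <= 0:
            raise ValueError("marginal sd must be positive")
        if self.family == "lognormal" and self.mean <= 0:
            raise ValueError("lognormal marginal requires positive mean")

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal for a lognormal marginal."""
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def latent_sigma(self) -> float:
        """Scale of this marginal's latent log/linear representation."""
        if self.family == "lognormal":
            return self.lognormal_params()[1]
        return self.sd


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: size, 12 marginals, and Spearman targets."""

    name: str
    n_lines: int
    marginals: dict[str, MarginalSpec]
    rank_correlation_targets: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        missing = set(FEATURES) - set(self.marginals)
        if missing:
            raise ValueError(f"group '{self.name}' missing marginals: {sorted(missing)}")
        for f1, f2, rho in self.rank_correlation_targets:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho out of range for ({f1}, {f2}): {rho}")


@dataclass(frozen=True)
class NoiseSpec:
    """Technical-replicate noise model and plate layout.

    Replicate counts default to the assay protocol: 12 flux wells per
    line, 8 fluorescence wells per dye per condition, ATP in triplicate
    per condition. Noise is a mean-one multiplicative lognormal with
    coefficient of variation ``technical_cv``; with probability
    ``outlier_rate`` a replicate is additionally shocked by a factor of
    ``outlier_scale``.
    """

    technical_cv: float = 0.08
    outlier_rate: float = 0.01
    outlier_scale: float = 3.0
    protein_mean: float = 0.1   # mg per line
    protein_cv: float = 0.15
    flux_wells: int = 12
    fluor_wells: int = 8
    atp_wells: int = 3
    flux_cycles: int = 3        # measurement cycles per injection phase
    nonmito_floor_frac: float = 0.15   # non-mito OCR as fraction of true baseline
    fluor_background_frac: float = 0.2  # FCCP background as fraction of true signal

    def __post_init__(self) -> None:
        for name in ("technical_cv", "outlier_rate", "protein_cv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: ATP standard curve used by the renderer: luminescence = a + b * amount.
ATP_STANDARD_INTERCEPT = 5000.0
ATP_STANDARD_SLOPE = 100.0
ATP_STANDARD_AMOUNTS = (0.0, 25.0, 50.0, 100.0, 200.0)


@dataclass(frozen=True)
class SyntheticConfig:
    groups: dict[str, GroupSpec]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    medium: str = "glucose"
    #: optional per-group number of lines that receive TMRM/MTG wells
    #: (None -> every line).
    tmrm_mtg_subset: dict[str, int] | None = None


# ---------------------------------------------------------------------------
# Default configuration: observed cohort summary statistics
# ---------------------------------------------------------------------------

# (mean, sd) per feature per group on the observed scale. ocr_spare and
# ocr_ecar_ratio are derived features: their entries are calibration /
# reference values (the spare SD is matched by construction; the ratio's
# moments are emergent).
_GROUP_SUMMARY = {
    "control": {
        "tmrm": (743.4, 298.5), "mtg": (5080.9, 2886.7),
        "ecar_base": (2035.9, 987.4), "ecar_aarot": (2631.1, 1164.4),
        "ocr_base": (2606.9, 1290.5), "ocr_oligo_sens": (2248.2, 1193.9),
        "ocr_spare": (1177.7, 1187.2), "ocr_max": (3784.6, 2166.9),
        "ocr_ecar_ratio": (1.5, 0.8), "atp_base": (271.6, 113.7),
        "atp_2dg_delta": (201.2, 87.8), "atp_oligo_delta": (-17.3, 78.1),
    },
    "sALS": {
        "tmrm": (948.3, 380.3), "mtg": (5918.7, 3939.6),
        "ecar_base": (2536.0, 1237.8), "ecar_aarot": (3126.2, 1366.6),
        "ocr_base": (3224.0, 1864.5), "ocr_oligo_sens": (2707.6, 1656.9),
        "ocr_spare": (1221.7, 1476.5), "ocr_max": (4445.7, 3048.2),
        "ocr_ecar_ratio": (1.4, 0.7), "atp_base": (312.1, 122.2),
        "atp_2dg_delta": (236.4, 92.1), "atp_oligo_delta": (-16.6, 72.4),
    },
    "PLS": {
        "tmrm": (1227.3, 456.7), "mtg": (3153.6, 2813.2),
        "ecar_base": (3909.1, 2175.4), "ecar_aarot": (4895.2, 2661.5),
        "ocr_base": (4504.6, 3259.3), "ocr_oligo_sens": (3947.9, 2892.3),
        "ocr_spare": (2292.5, 1563.6), "ocr_max": (6797.1, 4247.2),
        "ocr_ecar_ratio": (1.2, 0.6), "atp_base": (271.1, 103.2),
        "atp_2dg_delta": (220.1, 81.4), "atp_oligo_delta": (24.1, 60.2),
    },
    "C9orf72": {
        "tmrm": (1153.0, 397.5), "mtg": (5616.9, 5911.8),
        "ecar_base": (3381.9, 2988.0), "ecar_aarot": (3426.1, 2425.9),
        "ocr_base": (3338.2, 1450.7), "ocr_oligo_sens": (2900.4, 1251.4),
        "ocr_spare": (1105.3, 1195.8), "ocr_max": (4443.5, 2339.5),
        "ocr_ecar_ratio": (1.8, 1.7), "atp_base": (296.1, 103.8),
        "atp_2dg_delta": (234.7, 94.6), "atp_oligo_delta": (18.6, 55.1),
    },
}

GROUP_SIZES = {"control": 91, "sALS": 171, "PLS": 34, "C9orf72": 13}
TMRM_MTG_SUBSET_SIZES = {"control": 41, "sALS": 127, "PLS": 33, "C9orf72": 10}

# Spearman correlation table: pair -> {group: (rho, significant)}. Pairs
# marked not-significant in the source analysis get a target of 0.
_SPEARMAN_TABLE: dict[tuple[str, str], dict[str, tuple[float, bool]]] = {
    ("atp_base", "atp_2dg_delta"): {
        "control": (0.922, True), "sALS": (0.924, True),
        "PLS": (0.941, True), "C9orf72": (0.648, False)},
    ("ecar_aarot", "ocr_max"): {
        "control": (0.638, True), "sALS": (0.683, True),
        "PLS": (0.826, True), "C9orf72": (0.489, False)},
    ("ecar_base", "ocr_base"): {
        "control": (0.234, False), "sALS": (0.574, True),
        "PLS": (0.551, True), "C9orf72": (0.170, False)},
    ("ocr_ecar_ratio", "atp_base"): {
        "control": (0.211, False), "sALS": (-0.017, False),
        "PLS": (-0.508, True), "C9orf72": (0.384, False)},
    ("ocr_ecar_ratio", "atp_2dg_delta"): {
        "control": (0.248, False), "sALS": (0.012, False),
        "PLS": (-0.491, True), "C9orf72": (0.264, False)},
    ("ocr_base", "atp_base"): {
        "control": (0.182, False), "sALS": (0.155, False),
        "PLS": (-0.434, True), "C9orf72": (0.445, False)},
    ("ecar_base", "atp_base"): {
        "control": (0.012, False), "sALS": (0.124, False),
        "PLS": (0.005, False), "C9orf72": (-0.148, False)},
}

SPEARMAN_PAIRS = tuple(_SPEARMAN_TABLE)

# Clinical covariate ranges (uniform sampling; machinery placeholders, no
# claim of clinical realism). Keys absent for a group -> missing values.
_CLINICAL_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "control": {"age_biopsy": (47, 83)},
    "sALS": {"age_onset": (26, 79), "age_biopsy": (27, 80), "alsfrs": (8, 47),
             "progression_rate": (0.06, 3.4), "fvc_pct": (6, 138), "bmi": (16.2, 39.7)},
    "PLS": {"age_onset": (32, 74), "age_biopsy": (41, 81), "alsfrs": (14, 44),
            "progression_rate": (0.07, 0.37), "fvc_pct": (31, 143), "bmi": (19, 34.6)},
    "C9orf72": {"age_onset": (40, 70), "age_biopsy": (38, 72), "alsfrs": (30, 41),
                "progression_rate": (0.24, 2.0), "fvc_pct": (38, 115), "bmi": (20.5, 50.4)},
}
# female:male and spinal:bulbar ratios -> probabilities
_P_FEMALE = {"control": 0.88 / 1.88, "sALS": 0.67 / 1.67,
             "PLS": 0.79 / 1.79, "C9orf72": 1.50 / 2.50}
_P_SPINAL = {"sALS": 1.98 / 2.98, "PLS": 2.67 / 3.67, "C9orf72": 3.00 / 4.00}

_LINE_PREFIX = {"control": "CTRL", "sALS": "SALS", "PLS": "PLS", "C9orf72": "C9"}


def default_config(seed: int = 0, use_tmrm_mtg_subset: bool = False) -> SyntheticConfig:
    """The calibrated default cohort: observed marginals and correlations.

    ``use_tmrm_mtg_subset`` restricts TMRM/MTG wells to the subcohort
    sizes in which those dyes were actually measured (41/127/33/10);
    by default every line receives all assays, yielding 309 complete
    12-feature profiles.
    """
    groups: dict[str, GroupSpec] = {}
    for name, summary in _GROUP_SUMMARY.items():
        marginals = {}
        for feat, (mean, sd) in summary.items():
            family = "normal" if feat == "atp_oligo_delta" else "lognormal"
            if feat in DERIVED_FEATURES:
                # reference/calibration entry; a derived feature can span 0
                family = "normal"
            marginals[feat] = MarginalSpec(family, mean, sd)
        targets = tuple(
            (f1, f2, rho if sig else 0.0)
            for (f1, f2), by_group in _SPEARMAN_TABLE.items()
            for rho, sig in [by_group[name]]
        )
        groups[name] = GroupSpec(name, GROUP_SIZES[name], marginals, targets)
    return SyntheticConfig(
        groups=groups,
        noise=NoiseSpec(),
        seed=seed,
        tmrm_mtg_subset=dict(TMRM_MTG_SUBSET_SIZES) if use_tmrm_mtg_subset else None,
    )


# ---------------------------------------------------------------------------
# Latent correlation construction
# ---------------------------------------------------------------------------

def _spearman_to_pearson(rho_s: float) -> float:
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _pearson_to_spearman(r: float) -> float:
    return (6.0 / math.pi) * math.asin(max(-1.0, min(1.0, r)) / 2.0)


def nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the PSD correlation matrices.

    Eigenvalues are clipped at ``eps`` and the diagonal rescaled to 1.
    Returns the repaired matrix and the largest absolute entry change.
    """
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    repaired = (v * np.clip(w, eps, None)) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.abs(repaired - sym).max())


def _ascent_sweeps(R: np.ndarray, free: list[tuple[int, int]],
                   n_iter: int, tol: float) -> None:
    """In-place cyclic single-entry log-det maximization over free entries.

    The per-entry optimum is the zero-partial-correlation value
    ``R[i,rest] @ inv(R[rest,rest]) @ R[rest,j]``; from a positive
    definite start each exact single-coordinate step keeps the matrix
    positive definite (log det is concave and increases monotonically).
    """
    k = len(R)
    ridge = 1e-10 * np.eye(k - 2)
    for _ in range(n_iter):
        delta = 0.0
        for i, j in free:
            rest = [m for m in range(k) if m not in (i, j)]
            A = R[np.ix_(rest, rest)] + ridge
            val = float(R[i, rest] @ np.linalg.solve(A, R[rest, j]))
            val = max(-0.999, min(0.999, val))
            delta = max(delta, abs(val - R[i, j]))
            R[i, j] = R[j, i] = val
        if delta < tol:
            break


def _maxdet_complete(R: np.ndarray, specified: np.ndarray,
                     n_iter: int = 100, tol: float = 1e-11) -> np.ndarray:
    """Maximum-determinant completion of the unspecified correlations.

    Unspecified entries are set so their partial correlations vanish,
    which leaves every specified entry untouched; for a chordal specified
    pattern with positive definite cliques this is the unique max-det PSD
    completion. A plain zero fill is not used because it can be
    indefinite, and the subsequent PSD repair would then distort the
    targeted entries.

    The ascent must start positive definite, so the specified entries are
    ramped in over a homotopy (free entries warm-started between steps);
    the zero-fill start is only used directly when already feasible.
    """
    k = len(R)
    free = [(i, j) for i in range(k) for j in range(i + 1, k) if not specified[i, j]]
    if not free:
        return R.copy()
    E = np.where(specified, R, 0.0) - np.diag(np.diag(R))  # specified off-diagonal part
    F = np.where(~specified, R, 0.0)
    F = F - np.diag(np.diag(F))

    def assemble(t: float) -> np.ndarray:
        out = np.eye(k) + t * E + F
        return out

    t = 1.0
    if np.linalg.eigvalsh(assemble(1.0)).min() <= 1e-8:
        t = 0.0
    work = assemble(min(t + 0.2, 1.0)) if t == 0.0 else assemble(1.0)
    t = min(t + 0.2, 1.0) if t == 0.0 else 1.0
    step = 0.2
    for _ in range(200):
        if np.linalg.eigvalsh(work).min() <= 1e-8:
            # overshot: back off the homotopy step
            t -= step
            step /= 2.0
            t = min(t + step, 1.0)
            work = np.eye(k) + t * E + F
            continue
        _ascent_sweeps(work, free, n_iter, tol)
        F = np.where(~specified, work, 0.0)
        F -= np.diag(np.diag(F))
        if t >= 1.0:
            return work
        t = min(t + step, 1.0)
        work = np.eye(k) + t * E + F
    return work


def latent_correlation(spec: GroupSpec) -> tuple[np.ndarray, dict]:
    """Latent-normal correlation matrix over the 10 sampled features.

    Three ingredients:

    1. direct Spearman targets between sampled features, sin-transformed;
    2. the baseline~maximal OCR correlation, calibrated so the derived
       spare-capacity SD matches its configured value (exact lognormal
       covariance inversion);
    3. targets involving the derived OCR/ECAR ratio, expressed through
       the ratio's latent representation
       ``(sigma_b*Z_base - sigma_e*Z_ecar) / sigma_r`` and solved for a
       free direct correlation when one exists; otherwise the implied
       value is accepted and its deviation recorded.

    Remaining pairs are filled by maximum-determinant (zero partial
    correlation) completion, which preserves the targets exactly; a final
    PSD projection is a numerical safety net and its (normally zero)
    repair magnitude is recorded.
    """
    idx = {f: i for i, f in enumerate(SAMPLED_FEATURES)}
    k = len(SAMPLED_FEATURES)
    R = np.eye(k)
    specified = np.eye(k, dtype=bool)
    info: dict = {"ratio_target_deviation": {}, "clipped": []}

    def set_pair(f1: str, f2: str, r: float) -> None:
        r = max(-0.99999, min(0.99999, r))
        R[idx[f1], idx[f2]] = R[idx[f2], idx[f1]] = r
        specified[idx[f1], idx[f2]] = specified[idx[f2], idx[f1]] = True

    ratio_targets = []
    for f1, f2, rho in spec.rank_correlation_targets:
        if "ocr_ecar_ratio" in (f1, f2):
            other = f2 if f1 == "ocr_ecar_ratio" else f1
            ratio_targets.append((other, rho))
        elif f1 in idx and f2 in idx:
            set_pair(f1, f2, _spearman_to_pearson(rho))

    # spare-capacity SD calibration via cov(base, max) of lognormals
    m_b, m_m = spec.marginals["ocr_base"], spec.marginals["ocr_max"]
    sd_spare = spec.marginals["ocr_spare"].sd
    cov_target = (m_b.sd**2 + m_m.sd**2 - sd_spare**2) / 2.0
    if m_b.family == "lognormal" and m_m.family == "lognormal":
        arg = 1.0 + cov_target / (m_b.mean * m_m.mean)
        if arg <= 0:
            raise ValueError("spare-capacity SD target is unattainable")
        r_bm = math.log(arg) / (m_b.latent_sigma() * m_m.latent_sigma())
    else:
        r_bm = cov_target / (m_b.sd * m_m.sd)
    if not -1.0 < r_bm < 1.0:
        info["clipped"].append(("ocr_base", "ocr_max", r_bm))
    set_pair("ocr_base", "ocr_max", r_bm)
    info["r_base_max"] = R[idx["ocr_base"], idx["ocr_max"]]

    # ratio-involving targets through the latent linear representation;
    # alternate solving with re-completion since solving may pin entries
    # the completion had previously filled
    s_b = spec.marginals["ocr_base"].latent_sigma()
    s_e = spec.marginals["ecar_base"].latent_sigma()
    r_be = R[idx["ocr_base"], idx["ecar_base"]]
    s_r = math.sqrt(max(s_b**2 + s_e**2 - 2 * r_be * s_b * s_e, 1e-12))
    solved_knob: dict[str, str] = {}
    for sweep in range(4):
        R = _maxdet_complete(R, specified)
        if not ratio_targets:
            break
        for other, rho in ratio_targets:
            target = _spearman_to_pearson(rho)
            b_free = (not specified[idx["ocr_base"], idx[other]]
                      or solved_knob.get(other) == "ocr_base")
            e_free = (not specified[idx["ecar_base"], idx[other]]
                      or solved_knob.get(other) == "ecar_base")
            r_bx = R[idx["ocr_base"], idx[other]]
            r_ex = R[idx["ecar_base"], idx[other]]
            if b_free:
                set_pair("ocr_base", other, (target * s_r + s_e * r_ex) / s_b)
                solved_knob[other] = "ocr_base"
            elif e_free:
                set_pair("ecar_base", other, (s_b * r_bx - target * s_r) / s_e)
                solved_knob[other] = "ecar_base"
            implied = (s_b * R[idx["ocr_base"], idx[other]]
                       - s_e * R[idx["ecar_base"], idx[other]]) / s_r
            info["ratio_target_deviation"][other] = _pearson_to_spearman(implied) - rho

    repaired, delta = nearest_psd(R)
    info["psd_repair_max_delta"] = delta
    return repaired, info


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_line_profiles(spec: GroupSpec, rng: np.random.Generator,
                         n: int | None = None) -> pd.DataFrame:
    """Draw ground-truth 12-feature profiles for ``n`` lines of a group.

    Copula draw over the 10 sampled features, then the derived identities
    are recomputed so every profile invariant holds exactly.
    """
    n = spec.n_lines if n is None else n
    corr, _ = latent_correlation(spec)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    Z = rng.standard_normal((n, len(SAMPLED_FEATURES))) @ L.T
    data: dict[str, np.ndarray] = {}
    for j, feat in enumerate(SAMPLED_FEATURES):
        m = spec.marginals[feat]
        if m.family == "lognormal":
            mu, sigma = m.lognormal_params()
            data[feat] = np.exp(mu + sigma * Z[:, j])
        else:
            data[feat] = m.mean + m.sd * Z[:, j]
    data["ocr_spare"] = data["ocr_max"] - data["ocr_base"]
    data["ocr_ecar_ratio"] = data["ocr_base"] / data["ecar_base"]
    return pd.DataFrame({f: data[f] for f in FEATURES})


# ---------------------------------------------------------------------------
# Plate rendering (inverse of the extraction pipeline)
# ---------------------------------------------------------------------------

def _noise_factors(rng: np.random.Generator, size: int, noise: NoiseSpec) -> np.ndarray:
    """Mean-one multiplicative replicate noise with sporadic outliers."""
    if noise.technical_cv > 0:
        sigma2 = math.log1p(noise.technical_cv**2)
        factors = np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size))
    else:
        factors = np.ones(size)
    if noise.outlier_rate > 0 and noise.outlier_scale != 1.0:
        hits = rng.random(size) < noise.outlier_rate
        factors = np.where(hits, factors * noise.outlier_scale, factors)
    return factors


def atp_standard_table() -> pd.DataFrame:
    """The renderer's (exactly linear) ATP standard curve."""
    amounts = np.array(ATP_STANDARD_AMOUNTS)
    return pd.DataFrame({
        "atp_amount": amounts,
        "luminescence": ATP_STANDARD_INTERCEPT + ATP_STANDARD_SLOPE * amounts,
    })


def render_plate_data(profile, noise: NoiseSpec, rng: np.random.Generator,
                      line_id: str = "L1", plate_id: str = "P1",
                      medium: str = "glucose",
                      include_fluorescence: bool = True) -> dict[str, pd.DataFrame]:
    """Render raw well records for one line from its ground-truth profile.

    Constructed so that with ``technical_cv = 0`` and ``outlier_rate = 0``
    the extraction pipeline recovers the profile exactly: flux wells carry
    the phase-level true OCR plus a non-mitochondrial floor (cancelled by
    background subtraction), fluorescence background wells carry only the
    FCCP-depolarized component, and ATP wells invert the standard curve.
    ECAR at the two phases the metrics never read (oligomycin, FCCP) is
    filled with plausible intermediate values.
    """
    p = dict(profile)
    protein = noise.protein_mean
    if noise.protein_cv > 0:
        sigma2 = math.log1p(noise.protein_cv**2)
        protein = protein * math.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2)))

    floor = noise.nonmito_floor_frac * p["ocr_base"] * protein
    ocr_true = {
        "baseline": p["ocr_base"] * protein + floor,
        "oligomycin": (p["ocr_base"] - p["ocr_oligo_sens"]) * protein + floor,
        "FCCP": p["ocr_max"] * protein + floor,
        "AA_Rot": floor,
    }
    ecar_true = {
        "baseline": p["ecar_base"] * protein,
        "oligomycin": 0.5 * (p["ecar_base"] + p["ecar_aarot"]) * protein,
        "FCCP": p["ecar_aarot"] * protein,
        "AA_Rot": p["ecar_aarot"] * protein,
    }
    n_rep = noise.flux_wells * len(FLUX_PHASES) * noise.flux_cycles
    ocr_noise = _noise_factors(rng, n_rep, noise)
    ecar_noise = _noise_factors(rng, n_rep, noise)
    flux_rows = []
    i = 0
    for well in range(1, noise.flux_wells + 1):
        for phase in FLUX_PHASES:
            for cycle in range(1, noise.flux_cycles + 1):
                flux_rows.append((line_id, plate_id, f"W{well:02d}", medium, phase,
                                  cycle, ocr_true[phase] * ocr_noise[i],
                                  ecar_true[phase] * ecar_noise[i], protein))
                i += 1
    flux = pd.DataFrame(flux_rows, columns=["line_id", "plate_id", "well_id", "medium",
                                            "phase", "cycle", "ocr_raw", "ecar_raw",
                                            "protein"])

    fluor_rows = []
    if include_fluorescence:
        for dye, feat in (("TMRM", "tmrm"), ("MTG", "mtg")):
            signal_total = p[feat] * protein
            background = noise.fluor_background_frac * signal_total
            for treated, true in ((False, signal_total + background), (True, background)):
                factors = _noise_factors(rng, noise.fluor_wells, noise)
                for w in range(1, noise.fluor_wells + 1):
                    fluor_rows.append((line_id, f"{dye[0]}{'B' if treated else 'S'}{w}",
                                       dye, treated, true * factors[w - 1], protein))
    fluor = pd.DataFrame(fluor_rows, columns=["line_id", "well_id", "dye",
                                              "fccp_treated", "rfu", "protein"])

    atp_per_mg = {
        "baseline": p["atp_base"],
        "dg2": p["atp_base"] - p["atp_2dg_delta"],
        "oligo": p["atp_base"] - p["atp_oligo_delta"],
    }
    atp_rows = []
    for condition in ATP_CONDITIONS:
        amount = atp_per_mg[condition] * protein
        lum_true = ATP_STANDARD_INTERCEPT + ATP_STANDARD_SLOPE * amount
        factors = _noise_factors(rng, noise.atp_wells, noise)
        for w in range(1, noise.atp_wells + 1):
            atp_rows.append((line_id, f"A{condition[:2]}{w}", condition,
                             max(lum_true * factors[w - 1], 0.0), protein))
    atp = pd.DataFrame(atp_rows, columns=["line_id", "well_id", "condition",
                                          "luminescence", "protein"])

    return {"flux": flux, "fluorescence": fluor, "atp": atp,
            "atp_standard": atp_standard_table()}


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _sample_clinical(group: str, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {c: np.full(n, np.nan) for c in ("age_onset", "age_biopsy", "alsfrs",
                                            "progression_rate", "fvc_pct", "bmi")}
    for col, (lo, hi) in _CLINICAL_RANGES.get(group, {}).items():
        cols[col] = np.round(rng.uniform(lo, hi, n), 2)
    sex = np.where(rng.random(n) < _P_FEMALE[group], "F", "M")
    if group in _P_SPINAL:
        onset_site = np.where(rng.random(n) < _P_SPINAL[group], "spinal", "bulbar")
    else:
        onset_site = np.full(n, "NA", dtype=object)
    cols.update({"sex": sex, "onset_site": onset_site,
                 "passage": rng.integers(5, 11, n).astype(float)})
    return pd.DataFrame(cols)


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate the full cohort: line metadata, well tables, and truth.

    Returns ``(cohort, truth)`` where ``truth`` holds the ground-truth
    profile per line (columns: line_id, group, 12 features). Fully
    deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    line_frames, flux_frames, fluor_frames, atp_frames, truth_frames = [], [], [], [], []
    for group in (g for g in ("control", "sALS", "PLS", "C9orf72") if g in config.groups):
        spec = config.groups[group]
        if spec.n_lines == 0:
            continue
        profiles = sample_line_profiles(spec, rng)
        line_ids = [f"{_LINE_PREFIX.get(group, group)}-{i + 1:03d}"
                    for i in range(spec.n_lines)]
        clin = _sample_clinical(group, spec.n_lines, rng)
        clin.insert(0, "line_id", line_ids)
        clin.insert(1, "group", group)
        line_frames.append(clin)
        truth = profiles.copy()
        truth.insert(0, "line_id", line_ids)
        truth.insert(1, "group", group)
        truth_frames.append(truth)

        n_fluor = (config.tmrm_mtg_subset or {}).get(group, spec.n_lines)
        for i, line_id in enumerate(line_ids):
            tables = render_plate_data(
                profiles.iloc[i], config.noise, rng, line_id=line_id,
                plate_id=f"{_LINE_PREFIX.get(group, group)}-PLATE",
                medium=config.medium, include_fluorescence=i < n_fluor,
            )
            flux_frames.append(tables["flux"])
            if len(tables["fluorescence"]):
                fluor_frames.append(tables["fluorescence"])
            atp_frames.append(tables["atp"])

    def _cat(frames, schema_cols):
        if not frames:
            return pd.DataFrame(columns=schema_cols)
        return pd.concat(frames, ignore_index=True)

    lines = _cat(line_frames, ["line_id", "group"])
    cols = ["line_id", "group", "sex", "age_onset", "age_biopsy", "alsfrs",
            "progression_rate", "fvc_pct", "bmi", "onset_site", "passage"]
    lines = lines[cols]
    cohort = Cohort(
        lines=lines,
        flux=_cat(flux_frames, ["line_id", "plate_id", "well_id", "medium", "phase",
                                "cycle", "ocr_raw", "ecar_raw", "protein"]),
        fluorescence=_cat(fluor_frames, ["line_id", "well_id", "dye", "fccp_treated",
                                         "rfu", "protein"]),
        atp=_cat(atp_frames, ["line_id", "well_id", "condition", "luminescence",
                              "protein"]),
        atp_standard=atp_standard_table(),
    ).validate()
    truth = _cat(truth_frames, ["line_id", "group", *FEATURES])
    return cohort, truth
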