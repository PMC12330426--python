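"""Synthetic resting-state cohorts with known ground-truth aging structure.

Every downstream stage — denoising, connectivity, brain-age regression, gap
association — is testable against this generator because the generator plants
the signals the pipeline is supposed to recover:

* **age-dependent connectivity**: a fixed random subset of component pairs
  ("aging edges") drifts linearly in correlation with a subject's *effective*
  age;
* **temporally switching states**: frames are drawn from a small set of
  covariance states visited by a first-order Markov chain, so windowed
  (dynamic) connectivity carries information that full-scan (static)
  connectivity averages away; the ``aging_mode`` options additionally allow
  the age signal to be state-specific or confined to the early part of the
  scan (time-on-scan nonstationarity), in which case static connectivity
  sees only a diluted version of what windowed connectivity time-resolves;
* **site effects**: each acquisition site adds a fixed per-component mean
  shift;
* **diagnosis-linked acceleration**: diagnosed subjects age effectively
  faster — their effective age is shifted by a constant number of years —
  on top of a continuous per-subject acceleration term, so the true brain-age
  gap (BAG) varies within diagnostic groups;
* **cognition coupling**: two abstract cognitive scores (attention vigilance,
  working memory) decrease linearly with true BAG plus independent noise.

Effective age = chronological age + diagnosis shift + individual acceleration;
true BAG = effective age − chronological age, exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidInputError
from .timecourse import TimecourseMatrix

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "build_age_covariance",
    "sample_state_sequence",
    "generate_subject",
    "generate_cognition",
    "generate_cohort",
    "nearest_psd_correlation",
    "random_correlation_matrix",
]


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a synthetic cohort.

    Defaults describe a healthy adult training cohort: ages spanning 22-100
    years, UK-Biobank-like scan geometry (490 frames at TR 0.735 s), aging
    signal on 15% of edges, three connectivity states, seven sites, and a
    +7-year effective-age shift for diagnosed subjects (no diagnosed subjects
    by default). ``aging_slope`` is in correlation units per year on affected
    edges; ``accel_sd`` is the SD (years) of the continuous per-subject aging
    acceleration (7 y, the scale of brain-age spreads reported for clinical
    populations); ``cognition_slope`` couples scores to true BAG (score units
    per year, negative), with ``cognition_noise_sd`` sized so the planted
    partial correlation is -0.3 (noise = |slope| * accel_sd * sqrt(1/r^2 - 1)).
    ``psd_repair_tol`` bounds how negative an eigenvalue the PSD repair will
    clip before refusing the construction outright.
    """

    n_subjects: int = 200
    n_components: int = 53
    n_frames: int = 490
    tr_seconds: float = 0.735
    age_range: tuple[float, float] = (22.0, 100.0)
    aging_edge_fraction: float = 0.15
    aging_slope: float = 0.005
    n_states: int = 3
    state_dwell_mean: float = 50.0
    state_delta: float = 0.2
    aging_mode: str = "shared"
    aging_envelope_fraction: float = 1.0
    base_shrink: float = 0.5
    psd_repair_tol: float = 2.0
    site_count: int = 7
    site_shift_sd: float = 0.1
    diagnosis_fraction: float = 0.0
    diagnosis_bag_shift: float = 7.0
    accel_sd: float = 7.0
    cognition_slope: float = -0.5
    cognition_noise_sd: float = 11.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise InvalidInputError("n_components must be >= 2")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidInputError("age_range must satisfy min < max")
        for name in ("aging_edge_fraction", "diagnosis_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {value}")
        if self.n_states < 1:
            raise InvalidInputError("n_states must be >= 1")
        if self.state_dwell_mean < 1:
            raise InvalidInputError("state_dwell_mean must be >= 1 frame")
        if self.tr_seconds <= 0:
            raise InvalidInputError("tr_seconds must be positive")
        if self.aging_mode not in ("shared", "state_specific", "early_scan"):
            raise InvalidInputError(
                "aging_mode must be 'shared' (age shifts every state identically), "
                "'state_specific' (each state ages its own edge partition) or "
                "'early_scan' (age shift confined to the first "
                "aging_envelope_fraction of frames)"
            )
        if not 0.0 < self.aging_envelope_fraction <= 1.0:
            raise InvalidInputError("aging_envelope_fraction must be in (0, 1]")

    @property
    def age_midpoint(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated cohort: one time-course matrix per phenotype row."""

    timecourses: list
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig
    edge_mask: np.ndarray = field(repr=False, default=None)
    base_cov: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.timecourses) != len(self.phenotypes):
            raise InvalidInputError(
                f"{len(self.timecourses)} time-course matrices for "
                f"{len(self.phenotypes)} phenotype rows"
            )


# ---------------------------------------------------------------------------
# covariance construction


def random_correlation_matrix(
    n: int, rng: np.random.Generator, shrink: float = 0.5
) -> np.ndarray:
    """Random well-conditioned correlation matrix.

    A Wishart-style draw converted to correlation form, then shrunk toward the
    identity by ``shrink`` so that planted age shifts have headroom before the
    matrix leaves the positive-semidefinite cone.
    """
    raw = rng.standard_normal((n, 2 * n))
    cov = raw @ raw.T / (2 * n)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    out = (1.0 - shrink) * corr + shrink * np.eye(n)
    np.fill_diagonal(out, 1.0)
    return out


def nearest_psd_correlation(
    matrix: np.ndarray, repair_tol: float = 0.5
) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix, unit diagonal restored.

    Eigenvalues are clipped at zero and the diagonal renormalized
    (``D^{-1/2} A D^{-1/2}``); a unit-diagonal PSD matrix is a valid
    correlation matrix. If the most negative eigenvalue is below
    ``-repair_tol`` the input is considered too far from the cone to repair
    meaningfully.
    """
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise InvalidInputError("covariance matrix must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(matrix)
    if eigvals[0] < -repair_tol:
        raise GenerationError(
            f"matrix eigenvalue {eigvals[0]:.3f} below -{repair_tol}; "
            "reduce aging_slope (or state_delta) so planted shifts stay "
            "closer to a valid correlation structure"
        )
    clipped = eigvecs @ np.diag(np.clip(eigvals, 0.0, None)) @ eigvecs.T
    diag = np.diag(clipped).copy()
    if np.any(diag <= 0):
        raise GenerationError("degenerate diagonal after PSD projection")
    scale = 1.0 / np.sqrt(diag)
    out = clipped * np.outer(scale, scale)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out


def build_age_covariance(
    effective_age: float,
    config: CohortConfig,
    edge_mask: np.ndarray,
    base_cov: np.ndarray,
) -> np.ndarray:
    """Age-modulated component covariance.

    Adds ``aging_slope * (effective_age - age midpoint)`` to every masked
    edge of ``base_cov`` and projects the result back to a valid correlation
    matrix. Deterministic in its inputs.
    """
    base_cov = np.asarray(base_cov, dtype=float)
    edge_mask = np.asarray(edge_mask, dtype=bool)
    if not np.allclose(base_cov, base_cov.T, atol=1e-10):
        raise InvalidInputError("base_cov must be symmetric")
    if not np.allclose(np.diag(base_cov), 1.0, atol=1e-8):
        raise InvalidInputError("base_cov must have unit diagonal")
    if not np.array_equal(edge_mask, edge_mask.T) or np.any(np.diag(edge_mask)):
        raise InvalidInputError("edge_mask must be symmetric with zero diagonal")
    shift = config.aging_slope * (effective_age - config.age_midpoint)
    shifted = base_cov + shift * edge_mask
    return nearest_psd_correlation(shifted, repair_tol=config.psd_repair_tol)


def build_edge_mask(
    n: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric boolean mask selecting a random ``fraction`` of off-diagonal edges."""
    iu, ju = np.triu_indices(n, k=1)
    n_edges = len(iu)
    n_pick = int(round(fraction * n_edges))
    picked = rng.choice(n_edges, size=n_pick, replace=False)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[picked], ju[picked]] = True
    return mask | mask.T


def partition_edge_mask(
    edge_mask: np.ndarray, n_states: int, rng: np.random.Generator
) -> list:
    """Split the aging-edge mask into per-state partitions (round-robin, shuffled).

    Used by ``aging_mode='state_specific'``: each connectivity state then
    carries the age signal only on its own edges, so the full-scan (static)
    average dilutes the signal by the state occupancy while windowed
    connectivity sees it at full strength.
    """
    n = edge_mask.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    on = np.flatnonzero(edge_mask[iu, ju])
    on = rng.permutation(on)
    masks = []
    for s in range(n_states):
        mask = np.zeros_like(edge_mask)
        sel = on[s::n_states]
        mask[iu[sel], ju[sel]] = True
        masks.append(mask | mask.T)
    return masks


def build_state_covariances(
    base_cov: np.ndarray,
    state_mask: np.ndarray,
    n_states: int,
    delta: float,
    rng: np.random.Generator,
) -> list:
    """Per-state base correlation matrices.

    All states perturb the same ``state_mask`` edges by independent
    +/-``delta`` offsets, so the dynamic windows see genuinely different
    connectivity across states while the static (time-averaged) picture
    stays close to ``base_cov``. The state edges are drawn separately from
    the aging edges: were they shared, random state-occupancy fluctuations
    would shift every aging edge coherently, acting as common-mode noise on
    the age signal that no amount of edge averaging can remove.
    """
    if n_states == 1 or delta == 0.0:
        return [nearest_psd_correlation(base_cov) for _ in range(n_states)]
    n = base_cov.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    on_edges = state_mask[iu, ju]
    states = []
    for _ in range(n_states):
        signs = rng.choice([-1.0, 1.0], size=on_edges.sum())
        offset = np.zeros((n, n))
        offset[iu[on_edges], ju[on_edges]] = delta * signs
        offset += offset.T
        states.append(nearest_psd_correlation(base_cov + offset))
    return states


# ---------------------------------------------------------------------------
# temporal structure


def sample_state_sequence(
    n_frames: int,
    n_states: int,
    dwell_mean: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov state sequence.

    Self-transition probability is ``1 - 1/dwell_mean`` (geometric dwell times
    with the requested mean); off-state transitions are uniform.
    """
    if n_states < 1:
        raise InvalidInputError("n_states must be >= 1")
    if dwell_mean < 1:
        raise InvalidInputError("dwell_mean must be >= 1")
    states = np.empty(n_frames, dtype=int)
    if n_states == 1:
        states.fill(0)
        return states
    p_stay = 1.0 - 1.0 / dwell_mean
    states[0] = rng.integers(n_states)
    switches = rng.random(n_frames - 1) >= p_stay
    jumps = rng.integers(1, n_states, size=n_frames - 1)
    for t in range(1, n_frames):
        if switches[t - 1]:
            states[t] = (states[t - 1] + jumps[t - 1]) % n_states
        else:
            states[t] = states[t - 1]
    return states


# ---------------------------------------------------------------------------
# per-subject generation


def _covariance_factors(covs: list) -> list:
    factors = []
    for cov in covs:
        try:
            factors.append(np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0])))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise GenerationError("singular state covariance") from exc
    return factors


def generate_subject(
    record: pd.Series,
    config: CohortConfig,
    shared: dict,
    rng: np.random.Generator,
) -> TimecourseMatrix:
    """Simulate one scan: state-switching, age-modulated Gaussian frames.

    ``shared`` carries the cohort-level structure drawn once per cohort:
    ``base_cov``, ``edge_mask``, ``state_covs`` (per-state base correlation
    matrices) and ``site_shifts`` (site x component mean offsets).
    """
    age = float(record["age"])
    lo, hi = config.age_range
    if not lo <= age <= hi:
        raise InvalidInputError(f"age {age} outside configured range {config.age_range}")
    effective_age = float(record["effective_age"])
    state_masks = shared.get("state_masks") or [shared["edge_mask"]] * len(
        shared["state_covs"]
    )
    covs = [
        build_age_covariance(effective_age, config, mask, state_base)
        for state_base, mask in zip(shared["state_covs"], state_masks)
    ]
    factors = _covariance_factors(covs)
    if config.aging_mode == "early_scan" and config.aging_envelope_fraction < 1.0:
        # age shift confined to the initial stretch of the scan; the
        # remainder samples the unshifted state covariances
        plain = [
            nearest_psd_correlation(base, repair_tol=config.psd_repair_tol)
            for base in shared["state_covs"]
        ]
        plain_factors = _covariance_factors(plain)
        cut = int(round(config.aging_envelope_fraction * config.n_frames))
    else:
        plain_factors = factors
        cut = config.n_frames
    states = sample_state_sequence(
        config.n_frames, config.n_states, config.state_dwell_mean, rng
    )
    early = np.arange(config.n_frames) < cut
    z = rng.standard_normal((config.n_frames, config.n_components))
    data = np.empty_like(z)
    for s in range(len(factors)):
        for phase_sel, factor in ((early, factors[s]), (~early, plain_factors[s])):
            sel = (states == s) & phase_sel
            if sel.any():
                data[sel] = z[sel] @ factor.T
    data += shared["site_shifts"][int(record["site_index"])]
    return TimecourseMatrix(
        data=data, tr_seconds=config.tr_seconds, subject_id=str(record["subject_id"])
    )


def generate_cognition(
    true_bag: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-vigilance and working-memory scores from true BAG.

    score = cognition_slope * true_bag + Gaussian noise; the two scores use
    independent noise draws. Intercepts are zero and the scores unit-free.
    """
    true_bag = np.asarray(true_bag, dtype=float)
    if not np.isfinite(config.cognition_slope):
        raise InvalidInputError("cognition_slope must be finite")
    attention = config.cognition_slope * true_bag + config.cognition_noise_sd * (
        rng.standard_normal(true_bag.shape)
    )
    working_memory = config.cognition_slope * true_bag + config.cognition_noise_sd * (
        rng.standard_normal(true_bag.shape)
    )
    return attention, working_memory


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort deterministically from ``config`` (including seed)."""
    rng = np.random.default_rng(config.seed)
    n, c = config.n_subjects, config.n_components

    base_cov = random_correlation_matrix(c, rng, shrink=config.base_shrink)
    edge_mask = build_edge_mask(c, config.aging_edge_fraction, rng)
    state_mask = build_edge_mask(c, config.aging_edge_fraction, rng)
    state_covs = build_state_covariances(
        base_cov, state_mask, config.n_states, config.state_delta, rng
    )
    if config.aging_mode == "state_specific" and config.n_states > 1:
        state_masks = partition_edge_mask(edge_mask, config.n_states, rng)
    else:
        state_masks = [edge_mask] * config.n_states
    site_shifts = config.site_shift_sd * rng.standard_normal((config.site_count, c))

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)  # 0 = female, 1 = male
    site_index = rng.integers(0, config.site_count, size=n)
    diagnosis = (rng.random(n) < config.diagnosis_fraction).astype(int)
    accel = config.accel_sd * rng.standard_normal(n)
    effective_age = ages + config.diagnosis_bag_shift * diagnosis + accel
    true_bag = effective_age - ages
    attention, working_memory = generate_cognition(true_bag, config, rng)

    width = max(4, len(str(n)))
    phenotypes = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "age": ages,
            "sex": np.where(sex == 1, "M", "F"),
            "site": [f"site{k + 1}" for k in site_index],
            "diagnosis": diagnosis,
            "attention": attention,
            "working_memory": working_memory,
        }
    )
    internal = phenotypes.assign(site_index=site_index, effective_age=effective_age)
    truth = pd.DataFrame(
        {
            "subject_id": phenotypes["subject_id"],
            "true_bag": true_bag,
            "true_effective_age": effective_age,
        }
    )

    shared = {
        "base_cov": base_cov,
        "edge_mask": edge_mask,
        "state_covs": state_covs,
        "state_masks": state_masks,
        "site_shifts": site_shifts,
    }
    timecourses = [
        generate_subject(internal.iloc[i], config, shared, rng) for i in range(n)
    ]
    return SyntheticCohort(
        timecourses=timecourses,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
        edge_mask=edge_mask,
        base_cov=base_cov,
    )
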