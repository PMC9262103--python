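"""Seeded synthetic data with known ground truth.

Generates behaviour-like tables (sub-domains with known low-rank latent
structure plus noise), connectivity-matrix stacks built from symmetric
rank-1 patterns, confounds, family block structure, missingness and
sign-scrambled variables — everything the pipeline consumes, with the truth
needed to verify each stage.

Cross-block modes are planted at exact population canonical correlations:
for a shared standard-normal mode variable z and independent factor noise
f0, setting f = (f0 + c·z)/sqrt(1+c²) with c = sqrt(ρ/(1-ρ)) on both sides
makes the cross-covariance between the factor blocks rank-one per mode and
the population canonical correlation exactly ρ (the linked factor is the
optimal direction).  Observation noise attenuates what is recoverable from
the observed variables by 1/sqrt(1+σ²_noise/σ²_signal) per block; the truth
object reports both the factor-level and the expected observed-level value.

All randomness flows through ``numpy.random.default_rng`` (PCG64) from a
single integer seed, so every dataset is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectivityStack
from .data import DomainPartition, SubjectTable

__all__ = [
    "DomainSpec",
    "ConnectomeSpec",
    "LinkSpec",
    "ConfoundSpec",
    "make_domain_block",
    "make_sm_table",
    "make_linked_dataset",
    "scramble_signs",
    "add_missingness",
    "study_shape_specs",
]


@dataclass
class DomainSpec:
    """One sub-domain: P variables carrying a true low-rank signal."""

    label: str
    n_vars: int
    true_rank: int
    signal_sd: tuple[float, ...] | float = 2.0  # per latent factor
    noise_sd: float = 0.5
    loading_sparsity: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.true_rank <= self.n_vars:
            raise ValueError("need 0 < true_rank <= n_vars")
        if np.isscalar(self.signal_sd):
            # descending spread so factor order is well defined
            top = float(self.signal_sd)
            self.signal_sd = tuple(
                top * (0.75**i) for i in range(self.true_rank)
            )
        self.signal_sd = tuple(float(s) for s in self.signal_sd)
        if len(self.signal_sd) != self.true_rank:
            raise ValueError("one signal sd per latent factor required")
        if min(self.signal_sd) <= 0 or self.noise_sd <= 0:
            raise ValueError("sds must be positive")
        if not 0 <= self.loading_sparsity <= 1:
            raise ValueError("loading_sparsity must be in [0, 1]")


@dataclass
class ConnectomeSpec:
    """Connectivity stack built from global symmetric rank-1 patterns.

    Each subject's R × R matrix is a pattern-score-weighted sum of
    ``n_patterns`` symmetric patterns u_k u_kᵀ plus symmetric edge noise,
    with unit diagonal.  Region sub-domains inherit rank ≈ n_patterns.
    """

    n_regions: int = 20
    n_patterns: int = 5
    pattern_sd: tuple[float, ...] | float = 3.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if np.isscalar(self.pattern_sd):
            top = float(self.pattern_sd)
            self.pattern_sd = tuple(
                top * (0.8**i) for i in range(self.n_patterns)
            )
        self.pattern_sd = tuple(float(s) for s in self.pattern_sd)
        if len(self.pattern_sd) != self.n_patterns:
            raise ValueError("one sd per pattern required")


@dataclass
class LinkSpec:
    """Planted cross-block modes.

    ``sm_factors[k]``/``bm_factors[k]`` name the (0-based) factor column of
    each block carrying mode k; default is factor k on both sides.
    """

    canonical_rhos: tuple[float, ...] = ()
    sm_factors: tuple[int, ...] | None = None
    bm_factors: tuple[int, ...] | None = None

    @property
    def n_modes(self) -> int:
        return len(self.canonical_rhos)

    def __post_init__(self) -> None:
        rhos = tuple(float(r) for r in self.canonical_rhos)
        if any(not 0 < r < 1 for r in rhos):
            raise ValueError(
                "canonical rhos must lie strictly in (0, 1); the achievable "
                "maximum at the factor level is 1"
            )
        if any(rhos[i] <= rhos[i + 1] for i in range(len(rhos) - 1)):
            raise ValueError("canonical rhos must be strictly decreasing")
        self.canonical_rhos = rhos
        if self.sm_factors is None:
            self.sm_factors = tuple(range(self.n_modes))
        if self.bm_factors is None:
            self.bm_factors = tuple(range(self.n_modes))
        if len(set(self.sm_factors)) != self.n_modes or len(
            set(self.bm_factors)
        ) != self.n_modes:
            raise ValueError("each mode needs its own factor on each side")


@dataclass
class ConfoundSpec:
    n_confounds: int = 3
    effect_sd: float = 0.3
    affected_fraction: float = 0.5


def _masked_orthonormal(
    P: int, r: int, sparsity: float, rng: np.random.Generator
) -> np.ndarray:
    """Random orthonormal P × r loadings, optionally sparsity-masked first."""
    L = rng.standard_normal((P, r))
    if sparsity > 0:
        mask = rng.random((P, r)) >= sparsity
        for c in range(r):  # never zero out a whole column
            if not mask[:, c].any():
                mask[rng.integers(P), c] = True
        L = L * mask
    Q, _ = np.linalg.qr(L)
    return Q[:, :r]


def make_domain_block(
    spec: DomainSpec,
    n_subjects: int,
    rng_seed: int = 0,
    scores: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One sub-domain block = scores · loadingsᵀ + noise; truth returned.

    ``scores`` may be supplied (n × rank, unit variance) to plant linked or
    family-structured factors; otherwise they are drawn i.i.d. standard
    normal.  Returns ``(block, true_loadings)``.
    """
    if n_subjects <= spec.true_rank:
        raise ValueError("need n_subjects > true_rank")
    rng = np.random.default_rng(rng_seed)
    if scores is None:
        scores = rng.standard_normal((n_subjects, spec.true_rank))
    scaled = scores * np.asarray(spec.signal_sd)
    loadings = _masked_orthonormal(
        spec.n_vars, spec.true_rank, spec.loading_sparsity, rng
    )
    noise = rng.normal(0.0, spec.noise_sd, (n_subjects, spec.n_vars))
    return scaled @ loadings.T + noise, loadings


def _family_ids(
    n_subjects: int, n_families: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    assignment = np.sort(rng.integers(0, n_families, n_subjects))
    ids = [f"fam{a:05d}" for a in assignment]
    return ids, assignment


def _latent(
    n: int,
    k: int,
    fam: np.ndarray,
    family_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance latent scores with a family-level random intercept."""
    ind = rng.standard_normal((n, k))
    if family_sd == 0:
        return ind
    eff = rng.standard_normal((fam.max() + 1, k)) * family_sd
    return (ind + eff[fam]) / np.sqrt(1.0 + family_sd**2)


def make_sm_table(
    domain_specs: list[DomainSpec],
    n_subjects: int,
    rng_seed: int = 0,
    factor_scores: np.ndarray | None = None,
    family_ids: list[str] | None = None,
) -> tuple[SubjectTable, DomainPartition, dict]:
    """Concatenate per-domain blocks into a table with its partition."""
    rng = np.random.default_rng(rng_seed)
    cols, names, mapping = [], [], {}
    truth: dict = {"loadings": {}, "factor_labels": []}
    start = 0
    for d, spec in enumerate(domain_specs):
        if factor_scores is not None:
            scores = factor_scores[:, start : start + spec.true_rank]
        else:
            scores = None
        block, loadings = make_domain_block(
            spec, n_subjects, rng_seed=int(rng.integers(2**31)), scores=scores
        )
        cols.append(block)
        truth["loadings"][spec.label] = loadings
        truth["factor_labels"] += [
            f"{spec.label}::factor_{i + 1}" for i in range(spec.true_rank)
        ]
        for v in range(spec.n_vars):
            name = f"{spec.label}_v{v + 1}"
            names.append(name)
            mapping[name] = spec.label
        start += spec.true_rank
    table = SubjectTable(
        values=np.hstack(cols),
        variable_names=names,
        subject_ids=[f"sub{i:05d}" for i in range(n_subjects)],
        family_ids=family_ids,
    )
    return table, DomainPartition(mapping=mapping), truth


def make_linked_dataset(
    domain_specs_sm: list[DomainSpec],
    connectome_spec: ConnectomeSpec,
    link: LinkSpec,
    n_subjects: int = 500,
    n_families: int | None = None,
    family_sd: float = 0.4,
    confound_spec: ConfoundSpec | None = None,
    rng_seed: int = 0,
) -> tuple[SubjectTable, ConnectivityStack, SubjectTable, list[str], dict]:
    """Linked behaviour table + connectivity stack with planted modes.

    Returns ``(sm_table, bm_stack, confounds, family_ids, truth)``.  The
    truth dict carries the latent factor scores of both blocks, the mode
    variables, the planted rhos (exact at the factor level) and the expected
    observed-level attenuation per mode.
    """
    rng = np.random.default_rng(rng_seed)
    if n_families is None:
        n_families = max(1, int(round(n_subjects / 1.8)))
    fam_ids, fam = _family_ids(n_subjects, n_families, rng)

    k_sm = sum(s.true_rank for s in domain_specs_sm)
    k_bm = connectome_spec.n_patterns
    if link.n_modes and (max(link.sm_factors) >= k_sm or max(link.bm_factors) >= k_bm):
        raise ValueError("linked factor index exceeds available factors")

    F = _latent(n_subjects, k_sm, fam, family_sd, rng)
    S = _latent(n_subjects, k_bm, fam, family_sd, rng)
    Z = _latent(n_subjects, max(link.n_modes, 1), fam, family_sd, rng)
    for k, rho in enumerate(link.canonical_rhos):
        c = np.sqrt(rho / (1.0 - rho))
        scale = np.sqrt(1.0 + c**2)
        F[:, link.sm_factors[k]] = (F[:, link.sm_factors[k]] + c * Z[:, k]) / scale
        S[:, link.bm_factors[k]] = (S[:, link.bm_factors[k]] + c * Z[:, k]) / scale

    confounds = None
    if confound_spec is not None and confound_spec.n_confounds > 0:
        C = rng.standard_normal((n_subjects, confound_spec.n_confounds))
        confounds = SubjectTable(
            values=C,
            variable_names=[
                f"conf_{i + 1}" for i in range(confound_spec.n_confounds)
            ],
            subject_ids=[f"sub{i:05d}" for i in range(n_subjects)],
        )

    sm_table, partition_sm, sm_truth = make_sm_table(
        domain_specs_sm,
        n_subjects,
        rng_seed=int(rng.integers(2**31)),
        factor_scores=F,
        family_ids=fam_ids,
    )

    # symmetric edge synthesis from rank-1 patterns
    R = connectome_spec.n_regions
    patterns = np.linalg.qr(rng.standard_normal((R, k_bm)))[0][:, :k_bm]
    mats = np.zeros((n_subjects, R, R))
    scaled_S = S * np.asarray(connectome_spec.pattern_sd)
    for k in range(k_bm):
        outer = np.outer(patterns[:, k], patterns[:, k])
        mats += scaled_S[:, k, None, None] * outer[None]
    noise = rng.normal(0.0, connectome_spec.noise_sd, (n_subjects, R, R))
    mats += (noise + noise.transpose(0, 2, 1)) / np.sqrt(2.0)
    for i in range(n_subjects):
        np.fill_diagonal(mats[i], 1.0)

    if confounds is not None:
        # linear confound effects on a random subset of observed columns
        n_aff = int(round(confound_spec.affected_fraction * sm_table.n_variables))
        affected = rng.choice(sm_table.n_variables, size=n_aff, replace=False)
        beta_sm = rng.normal(
            0.0, confound_spec.effect_sd, (confound_spec.n_confounds, n_aff)
        )
        values = sm_table.values.copy()
        values[:, affected] += confounds.values @ beta_sm
        sm_table = sm_table.with_values(values)
        beta_bm = rng.normal(
            0.0, confound_spec.effect_sd, (confound_spec.n_confounds, k_bm)
        )
        eff = confounds.values @ beta_bm
        for k in range(k_bm):
            outer = np.outer(patterns[:, k], patterns[:, k])
            off = outer - np.diag(np.diag(outer))
            mats += eff[:, k, None, None] * off[None]

    stack = ConnectivityStack(
        matrices=mats,
        region_labels=[f"region_{i + 1}" for i in range(R)],
        subject_ids=list(sm_table.subject_ids),
        family_ids=fam_ids,
    )

    atten_sm = []
    atten_bm = []
    sd_index: list[tuple[float, float]] = []  # (signal_sd, noise_sd) per factor
    for spec in domain_specs_sm:
        sd_index.extend((s, spec.noise_sd) for s in spec.signal_sd)
    for k in range(link.n_modes):
        s_sm, nz_sm = sd_index[link.sm_factors[k]]
        s_bm = connectome_spec.pattern_sd[link.bm_factors[k]]
        atten_sm.append(s_sm / np.sqrt(s_sm**2 + nz_sm**2))
        atten_bm.append(s_bm / np.sqrt(s_bm**2 + connectome_spec.noise_sd**2))
    truth = {
        "canonical_rhos": link.canonical_rhos,
        "sm_factor_scores": F,
        "bm_pattern_scores": S,
        "mode_scores": Z[:, : link.n_modes],
        "sm_linked_factors": link.sm_factors,
        "bm_linked_patterns": link.bm_factors,
        "patterns": patterns,
        "partition_sm": partition_sm,
        "sm_truth": sm_truth,
        "observed_rho_expected": tuple(
            link.canonical_rhos[k] * atten_sm[k] * atten_bm[k]
            for k in range(link.n_modes)
        ),
        "family_sd": family_sd,
    }
    return sm_table, stack, confounds, fam_ids, truth


def scramble_signs(
    table: SubjectTable, fraction: float, rng_seed: int = 0
) -> tuple[SubjectTable, list[str]]:
    """Negate a random fraction of columns; returns which were flipped."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_flip = int(round(fraction * table.n_variables))
    flip_idx = rng.choice(table.n_variables, size=n_flip, replace=False)
    values = table.values.copy()
    values[:, flip_idx] = -values[:, flip_idx]
    flipped = sorted(table.variable_names[i] for i in flip_idx)
    return table.with_values(values), flipped


def add_missingness(
    table: SubjectTable, fraction: float, rng_seed: int = 0
) -> SubjectTable:
    """Blank a random fraction of entries (missing completely at random)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    values = table.values.copy()
    mask = rng.random(values.shape) < fraction
    values[mask] = np.nan
    return SubjectTable(
        values=values,
        variable_names=list(table.variable_names),
        subject_ids=list(table.subject_ids),
        family_ids=None if table.family_ids is None else list(table.family_ids),
    )


#: (label, n_vars, true_rank) for the 14 behaviour-like sub-domains of the
#: desk-scale preset; factor counts sum to 62 across 218 variables.
_STUDY_SHAPE_DOMAINS = [
    ("demographics", 7, 1),
    ("physical_health", 8, 3),
    ("female_health", 5, 5),
    ("family_history", 5, 2),
    ("psychiatry", 44, 10),
    ("sensory", 12, 7),
    ("drug_use", 11, 1),
    ("alcohol_use", 28, 5),
    ("tobacco_use", 10, 1),
    ("alertness", 9, 1),
    ("cognition", 44, 14),
    ("emotion", 23, 8),
    ("motor", 7, 3),
    ("personality", 5, 1),
]


def study_shape_specs() -> tuple[list[DomainSpec], ConnectomeSpec, LinkSpec]:
    """Desk-scale preset: 14 behaviour sub-domains, 20-region connectome.

    Two cross-block modes are planted at ρ = 0.75 and 0.55, carried by the
    leading cognition factor and the tobacco-use factor on the behaviour
    side and the two strongest connectivity patterns on the brain side.
    """
    sm_specs = [
        DomainSpec(label=label, n_vars=p, true_rank=r, signal_sd=3.0, noise_sd=0.6)
        for (label, p, r) in _STUDY_SHAPE_DOMAINS
    ]
    bm_spec = ConnectomeSpec(n_regions=20, n_patterns=5, pattern_sd=3.0,
                             noise_sd=0.3)
    factor_index = {}
    start = 0
    for label, _, r in _STUDY_SHAPE_DOMAINS:
        factor_index[label] = start
        start += r
    link = LinkSpec(
        canonical_rhos=(0.75, 0.55),
        sm_factors=(factor_index["cognition"], factor_index["tobacco_use"]),
        bm_factors=(0, 1),
    )
    return sm_specs, bm_spec, link
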