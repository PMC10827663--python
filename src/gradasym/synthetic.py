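"""Synthetic multi-site cohorts with planted ground truth.

The generator emulates the structure of a multi-site autism resting-state
study: two diagnostic groups (autism / NAI) across 5 sites, male cohort
aged 5-40, with group offsets in FIQ and head motion. Connectomes are
generated from a low-rank latent model: each hemisphere carries per-parcel
scores on k latent gradient axes, and the Fisher-z connectome is a scaled
Gram matrix of those scores (inner products squashed through tanh to
(-1, 1) and Fisher re-expanded, which composes to the identity, so the
z-matrix is exactly the scaled Gram plus noise). Effects are planted
where the downstream claims live:

* a group difference in homotopic asymmetry (opposite-signed shifts on the
  left and right members of designated homolog pairs, autism only),
* group-specific age slopes on designated pairs (an age-by-group
  interaction),
* additive and multiplicative per-site batch effects on the z values,
* ADOS symptom scores linearly coupled to a sparse set of intra-hemispheric
  asymmetry features (RRB decoupled).

Everything is driven by one seed and regenerates bit-identically.

Two routes are exposed. ``simulate_connectomes`` produces full hemispheric
blocks and exercises the embedding pipeline end to end.
``simulate_ai_features`` emits the asymmetry-index feature matrix directly
from the latent model (same effect definitions, exact effect sizes in
standardized AI units); replicate-heavy power studies use this route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .connectome import HemiBlocks
from .errors import ParameterError
from .io_core import (
    NETWORKS_12,
    CohortTable,
    ParcellationScheme,
    apply_exclusion_flags,
    canonical_parcellation_table,
)

GRADIENT_LABELS = ("G1", "G2", "G3")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    template_left: np.ndarray  # n_pairs x k latent axes, left hemisphere
    template_right: np.ndarray
    eigen_weights: np.ndarray  # latent axis weights, decreasing
    asym_effect_pairs: np.ndarray  # homolog-pair indices with a group AI difference
    asym_effect_gradient: int  # which latent axis carries it (0-based)
    asym_effect_size: float  # standardized mean difference on AI (NAI minus autism)
    age_effect_pairs: np.ndarray  # pairs with group-specific age slopes
    age_effect_gradient: int
    age_slope_by_group: dict[str, float]  # AI units per year of (age - midpoint)
    site_shift: dict[str, float]
    site_scale: dict[str, float]
    subject_noise_sd: float  # per-hemisphere latent score noise (AI noise sd * sqrt(2)/2... see below)
    trait_weights: np.ndarray | None = None  # sparse over (pair, gradient) intra features
    trait_noise_sd: float | None = None
    baseline_asymmetry: np.ndarray | None = None  # n_pairs x k shared leftward baseline

    @property
    def n_pairs(self) -> int:
        return self.template_left.shape[0]

    @property
    def k(self) -> int:
        return self.template_left.shape[1]


# ---------------------------------------------------------------------------
# parcellation and phenotypes
# ---------------------------------------------------------------------------

def make_parcellation(
    n_per_hemi: int = 180, n_networks: int = 12, seed: int = 0
) -> ParcellationScheme:
    """Random balanced network assignment, mirrored so homologs share a network."""
    if n_networks > n_per_hemi:
        raise ParameterError(
            f"n_networks={n_networks} cannot exceed n_per_hemi={n_per_hemi}"
        )
    if n_networks < 1:
        raise ParameterError("n_networks must be >= 1")
    rng = np.random.default_rng(seed)
    labels = list(NETWORKS_12[:n_networks]) if n_networks <= 12 else [
        f"N{i:02d}" for i in range(n_networks)
    ]
    reps = -(-n_per_hemi // n_networks)  # ceil division: balanced-ish blocks
    nets = np.tile(labels, reps)[:n_per_hemi]
    rng.shuffle(nets)
    table = canonical_parcellation_table(n_per_hemi, nets)
    return ParcellationScheme(table, networks=tuple(labels))


def simulate_cohort(
    n_per_group: int = 70,
    n_sites: int = 5,
    age_range: tuple[float, float] = (5.0, 40.0),
    seed: int = 0,
    fiq_group_offset: float = -8.0,
    fd_group_offset: float = 0.02,
    config: PipelineConfig | None = None,
) -> CohortTable:
    """Phenotype table: balanced groups across sites, uniform ages.

    Autism subjects have lower FIQ and higher mean framewise displacement
    on average, mirroring the group differences typically reported.
    """
    if n_per_group < 1 or n_sites < 1:
        raise ParameterError("n_per_group and n_sites must be >= 1")
    lo, hi = age_range
    if lo >= hi:
        raise ParameterError(f"degenerate age range {age_range}")
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group in ("autism", "NAI"):
        for i in range(n_per_group):
            site = f"site{i % n_sites:02d}"  # round-robin: groups balanced per site
            age = rng.uniform(lo, hi)
            fiq = rng.normal(110.0, 12.0) + (fiq_group_offset if group == "autism" else 0.0)
            fd = abs(rng.normal(0.10, 0.05)) + (fd_group_offset if group == "autism" else 0.0)
            rows.append(
                {
                    "subject_id": f"sub-{sid:04d}",
                    "group": group,
                    "age": age,
                    "site": site,
                    "fiq": fiq,
                    "mean_fd": fd,
                    "ados_total": np.nan,
                    "ados_comm": np.nan,
                    "ados_social": np.nan,
                    "ados_rrb": np.nan,
                }
            )
            sid += 1
    table = apply_exclusion_flags(pd.DataFrame(rows), config)
    return CohortTable(table)


# ---------------------------------------------------------------------------
# latent templates and truth presets
# ---------------------------------------------------------------------------

def _smooth_axes(n: int, k: int, rng: np.random.Generator, jitter: float = 0.05) -> np.ndarray:
    """k smooth, mutually orthonormal axes over n parcels (low-frequency cosines
    plus a small seeded perturbation, then QR)."""
    x = np.linspace(0.0, 1.0, n)
    cols = [np.cos(np.pi * (j + 1) * x) for j in range(k)]
    T = np.column_stack(cols)
    T = T + jitter * rng.standard_normal((n, k))
    q, r = np.linalg.qr(T)
    # sign convention from the QR diagonal, so the axes are seed-stable
    return q * np.sign(np.diag(r))


def calibrate_template(
    n_pairs: int = 180,
    k: int = 3,
    eigen_weights: np.ndarray | None = None,
    seed: int = 0,
    n_iter: int = 8,
    n_computed: int = 10,
    density: float = 0.10,
    alpha: float = 0.5,
) -> np.ndarray:
    """Latent axes that the gradient pipeline can reproduce.

    Gradients are, by definition, what the embedding pipeline measures; an
    arbitrary smooth axis is generally not in the image of
    sparsify -> affinity -> diffusion map, so a cohort built on arbitrary
    axes has no exact ground-truth gradients. This routine iterates the
    pipeline to a reproducing template: starting from smooth perturbed
    cosines, it embeds the noise-free Gram block, Procrustes-aligns the
    components back onto the current axes, orthonormalizes, and repeats,
    keeping the iterate that best reproduces itself. The result is a
    deterministic function of the seed.
    """
    from .gradients import (  # local import; gradients does not import synthetic
        GradientTemplate,
        align_to_template,
        cosine_affinity,
        diffusion_embedding,
        sparsify_rows,
    )

    w = np.asarray(eigen_weights) if eigen_weights is not None else np.array(
        [1.0, 0.6, 0.35][:k]
    )
    rng = np.random.default_rng(seed)
    T = _smooth_axes(n_pairs, k, rng, jitter=0.08)

    def aligned_components(T: np.ndarray) -> np.ndarray:
        Z = GRAM_SCALE * (T * w) @ T.T + GRAM_OFFSET
        np.fill_diagonal(Z, 0.0)
        gset = diffusion_embedding(
            cosine_affinity(sparsify_rows(Z, density)), alpha, n_computed, 0.0
        )
        tmpl = np.zeros((n_pairs, n_computed))
        tmpl[:, :k] = T
        return align_to_template(gset, GradientTemplate(tmpl)).components[:, :k]

    def self_consistency(T: np.ndarray, A: np.ndarray) -> float:
        num = np.abs((A * T).sum(axis=0))
        den = np.linalg.norm(A, axis=0) * np.linalg.norm(T, axis=0)
        return float(np.min(num / den))

    best_T, best_score = T, -np.inf
    for _ in range(n_iter):
        A = aligned_components(T)
        score = self_consistency(T, A)
        if score > best_score:
            best_T, best_score = T, score
        Ac = A - A.mean(axis=0)
        q, r = np.linalg.qr(Ac)
        T = q * np.sign(np.diag(r))
    return best_T


def default_truth(
    scheme: ParcellationScheme,
    seed: int = 0,
    k: int = 3,
    asym_effect_size: float = 0.8,
    n_effect_pairs: int = 10,
    asym_effect_gradient: int = 0,
    age_slope_nai: float = 0.15,
    age_slope_autism: float = 0.0,
    n_age_pairs: int = 10,
    age_effect_gradient: int = 2,
    subject_noise_sd: float = 1.0,
    site_shift_sd: float = 0.3,
    site_scale_spread: float = 0.2,
    n_sites: int = 5,
    effect_network: str = "Lan",
    baseline_sd: float = 0.3,
    calibrate: bool = False,
) -> GroundTruth:
    """Build a ground-truth record with effects planted in one network.

    Group-difference pairs are drawn from ``effect_network`` (the language
    network by default); age-interaction pairs likewise. ``subject_noise_sd``
    is the standardized unit: planted effect sizes are in multiples of the
    between-subject AI standard deviation.
    """
    rng = np.random.default_rng(seed)
    n_pairs = scheme.n_pairs
    weights = np.array([1.0, 0.6, 0.35][:k])
    if calibrate:
        template = calibrate_template(n_pairs, k, weights, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    else:
        template = _smooth_axes(n_pairs, k, rng)
    # shared baseline leftward asymmetry: smooth, small, identical in both groups
    baseline = baseline_sd * _smooth_axes(n_pairs, k, rng)

    nets = scheme.pair_networks
    candidates = np.flatnonzero(nets == effect_network)
    if candidates.size < max(n_effect_pairs, n_age_pairs):
        candidates = np.arange(n_pairs)
    effect_pairs = np.sort(rng.choice(candidates, size=n_effect_pairs, replace=False))
    age_pairs = np.sort(rng.choice(candidates, size=n_age_pairs, replace=False))

    sites = [f"site{i:02d}" for i in range(n_sites)]
    site_shift = {s: float(rng.normal(0.0, site_shift_sd)) for s in sites}
    site_scale = {
        s: float(rng.uniform(1.0 - site_scale_spread / 2, 1.0 + site_scale_spread / 2))
        for s in sites
    }
    return GroundTruth(
        template_left=template,
        template_right=template.copy(),
        eigen_weights=weights,
        asym_effect_pairs=effect_pairs,
        asym_effect_gradient=asym_effect_gradient,
        asym_effect_size=asym_effect_size,
        age_effect_pairs=age_pairs,
        age_effect_gradient=age_effect_gradient,
        age_slope_by_group={"NAI": age_slope_nai, "autism": age_slope_autism},
        site_shift=site_shift,
        site_scale=site_scale,
        subject_noise_sd=subject_noise_sd,
        baseline_asymmetry=baseline,
    )


def reference_template(truth: GroundTruth, n_computed: int = 10):
    """Alignment target built from the planted axes.

    The synthetic analog of an external group-level reference (in the real
    study, gradients are aligned to an independent HCP-derived template,
    not to the cohort itself). Planted axes fill the first k columns; the
    remainder are zero, which Procrustes treats as don't-care directions.
    """
    from .gradients import GradientTemplate

    n = truth.n_pairs
    comp = np.zeros((n, max(n_computed, truth.k)))
    comp[:, : truth.k] = truth.template_left
    return GradientTemplate(components=comp)


# ---------------------------------------------------------------------------
# direct asymmetry-feature route (exact planted effect sizes)
# ---------------------------------------------------------------------------

def _age_centered(cohort: CohortTable) -> np.ndarray:
    age = np.asarray(cohort.table["age"], dtype=float)
    return age - age.mean()


def simulate_ai_features(
    cohort: CohortTable,
    scheme: ParcellationScheme,
    truth: GroundTruth,
    seed: int = 0,
    apply_site_effects: bool = True,
) -> np.ndarray:
    """Asymmetry-index features straight from the latent model.

    Returns an array of shape (n_subjects, n_pairs, k): per-subject AI =
    baseline asymmetry + planted group shift (autism lowered by
    ``asym_effect_size`` standardized units on the effect pairs/gradient)
    + group-specific age slope on the age pairs + iid subject noise, then
    per-site location/scale batch effects.
    """
    rng = np.random.default_rng(seed)
    t = cohort.table
    n = len(t)
    n_pairs, k = truth.n_pairs, truth.k
    sd = truth.subject_noise_sd
    ai = np.zeros((n, n_pairs, k))
    if truth.baseline_asymmetry is not None:
        ai += truth.baseline_asymmetry[None, :, :]
    # between-subject variation: half the variance is shared low-rank
    # structure (common patterns with subject loadings, as in real
    # asymmetry maps), half independent per feature; unit marginal
    # variance on average
    r_struct = 20
    basis = rng.standard_normal((r_struct, n_pairs * k))
    basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    loadings = rng.standard_normal((n, r_struct))
    structured = (loadings @ basis).reshape(n, n_pairs, k) * np.sqrt(n_pairs * k / r_struct)
    structured /= structured.std()
    ai += sd * (np.sqrt(0.5) * structured
                + np.sqrt(0.5) * rng.standard_normal((n, n_pairs, k)))

    is_autism = (np.asarray(t["group"]) == "autism")
    shift = truth.asym_effect_size * sd
    ai[np.ix_(is_autism, truth.asym_effect_pairs, [truth.asym_effect_gradient])] -= shift

    age_c = _age_centered(cohort)
    for grp, slope in truth.age_slope_by_group.items():
        if slope == 0.0:
            continue
        rows = np.flatnonzero(np.asarray(t["group"]) == grp)
        ai[np.ix_(rows, truth.age_effect_pairs, [truth.age_effect_gradient])] += (
            slope * sd * age_c[rows][:, None, None]
        )

    if apply_site_effects:
        sites = np.asarray(t["site"])
        for s in np.unique(sites):
            rows = np.flatnonzero(sites == s)
            sc = truth.site_scale.get(s, 1.0)
            sh = truth.site_shift.get(s, 0.0)
            ai[rows] = sc * ai[rows] + sh
    return ai


def flatten_features(ai: np.ndarray) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """(subjects, pairs, k) -> (subjects, pairs * k) with (pair, gradient) labels."""
    n, n_pairs, k = ai.shape
    X = ai.reshape(n, n_pairs * k)
    labels = [(p, GRADIENT_LABELS[g] if g < 3 else f"G{g+1}") for p in range(n_pairs) for g in range(k)]
    return X, labels


# ---------------------------------------------------------------------------
# connectome route (full pipeline exercise)
# ---------------------------------------------------------------------------

#: Gram-matrix scale and additive offset for the synthetic Fisher-z blocks.
#: The squashing of latent inner products is tanh into (-1, 1); composed with
#: the downstream Fisher z = atanh this is the identity, so these constants
#: act directly on the z values.
GRAM_SCALE = 18.0
GRAM_OFFSET = 0.25

#: default between-subject AI standard deviation in latent-axis units; the
#: fixed unit in which planted effects are expressed on the connectome route
LATENT_AI_SD = 0.03


@dataclass
class SyntheticCohort:
    """A cohort plus its connectomes and the planted truth."""

    cohort: CohortTable
    scheme: ParcellationScheme
    blocks: dict[str, HemiBlocks] = field(default_factory=dict)
    truth: GroundTruth | None = None


def _subject_latents(
    cohort: CohortTable, truth: GroundTruth, seed: int, latent_noise_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject left/right latent score matrices (n, n_pairs, k).

    The planted AI shift is realized as opposite-signed shifts on the left
    and right homolog (half each), so the homotopic difference carries the
    full effect while within-hemisphere profiles move minimally. Effect
    sizes are expressed in the fixed unit ``LATENT_AI_SD`` (the default
    between-subject AI sd), so a planted shift survives a noise-free run.
    """
    rng = np.random.default_rng(seed)
    t = cohort.table
    n = len(t)
    n_pairs, k = truth.n_pairs, truth.k
    half = 0.5 * latent_noise_sd * np.sqrt(2.0)  # AI noise sd = latent_noise_sd
    UL = truth.template_left[None] + half * rng.standard_normal((n, n_pairs, k))
    UR = truth.template_right[None] + half * rng.standard_normal((n, n_pairs, k))
    unit = LATENT_AI_SD
    if truth.baseline_asymmetry is not None:
        UL = UL + 0.5 * unit * truth.baseline_asymmetry[None]
        UR = UR - 0.5 * unit * truth.baseline_asymmetry[None]

    is_autism = np.asarray(t["group"]) == "autism"
    shift = 0.5 * truth.asym_effect_size * unit
    g = truth.asym_effect_gradient
    UL[np.ix_(is_autism, truth.asym_effect_pairs, [g])] -= shift
    UR[np.ix_(is_autism, truth.asym_effect_pairs, [g])] += shift

    age_c = _age_centered(cohort)
    ga = truth.age_effect_gradient
    for grp, slope in truth.age_slope_by_group.items():
        if slope == 0.0:
            continue
        rows = np.flatnonzero(np.asarray(t["group"]) == grp)
        delta = 0.5 * slope * unit * age_c[rows][:, None, None]
        UL[np.ix_(rows, truth.age_effect_pairs, [ga])] += delta
        UR[np.ix_(rows, truth.age_effect_pairs, [ga])] -= delta
    return UL, UR


def simulate_connectomes(
    cohort: CohortTable,
    scheme: ParcellationScheme,
    truth: GroundTruth | None = None,
    seed: int = 0,
    latent_noise_sd: float = LATENT_AI_SD,
    edge_noise_sd: float = 0.02,
    apply_site_effects: bool = True,
) -> SyntheticCohort:
    """Per-subject hemispheric Fisher-z blocks from the latent gradient model.

    Block z-values are ``GRAM_SCALE * U_a diag(w) U_b^T + GRAM_OFFSET`` plus
    symmetric edge noise; site batch effects act as location/scale changes
    on the z values. ``latent_noise_sd`` is in template-axis units (the
    axes are unit-norm over 180 parcels, entries ~0.07 in magnitude, so the
    default is a visible but embedding-survivable perturbation).
    """
    if truth is None:
        truth = default_truth(scheme, seed=seed)
    if truth.asym_effect_pairs.size and truth.asym_effect_pairs.max() >= scheme.n_pairs:
        raise ParameterError("effect pair index out of range for this parcellation")
    UL, UR = _subject_latents(cohort, truth, seed, latent_noise_sd)
    w = truth.eigen_weights
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    t = cohort.table
    blocks: dict[str, HemiBlocks] = {}
    for i, sid in enumerate(t["subject_id"]):
        ul = UL[i] * w
        ur = UR[i] * w
        z_ll = GRAM_SCALE * ul @ UL[i].T + GRAM_OFFSET
        z_rr = GRAM_SCALE * ur @ UR[i].T + GRAM_OFFSET
        z_lr = GRAM_SCALE * ul @ UR[i].T + GRAM_OFFSET
        if edge_noise_sd > 0:
            e_ll = rng.standard_normal(z_ll.shape)
            e_rr = rng.standard_normal(z_rr.shape)
            e_lr = rng.standard_normal(z_lr.shape)
            z_ll = z_ll + edge_noise_sd * (e_ll + e_ll.T) / np.sqrt(2.0)
            z_rr = z_rr + edge_noise_sd * (e_rr + e_rr.T) / np.sqrt(2.0)
            z_lr = z_lr + edge_noise_sd * e_lr
        z_rl = z_lr.T.copy()
        if apply_site_effects:
            site = t["site"].iloc[i]
            sc = truth.site_scale.get(site, 1.0)
            sh = truth.site_shift.get(site, 0.0)
            z_ll, z_rr, z_lr, z_rl = (
                sc * z_ll + sh, sc * z_rr + sh, sc * z_lr + sh, sc * z_rl + sh,
            )
        for z in (z_ll, z_rr):
            np.fill_diagonal(z, 0.0)
        blocks[str(sid)] = HemiBlocks(LL=z_ll, LR=z_lr, RL=z_rl, RR=z_rr)
    return SyntheticCohort(cohort=cohort, scheme=scheme, blocks=blocks, truth=truth)


def simulate_timeseries(
    blocks_latent: np.ndarray, n_timepoints: int = 200, noise_sd: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Optional time-series emitter: latent scores x random temporal loadings
    + noise. Only exists to exercise the Pearson-correlation connectome path."""
    rng = np.random.default_rng(seed)
    n_parcels, k = blocks_latent.shape
    loadings = rng.standard_normal((n_timepoints, k))
    return loadings @ blocks_latent.T + noise_sd * rng.standard_normal(
        (n_timepoints, n_parcels)
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def noise_sd_for_r2(signal: np.ndarray, r2: float) -> float:
    """Noise sd making the generating regression's population R^2 equal r2."""
    if not (0.0 < r2 < 1.0):
        raise ParameterError(f"r2 must be in (0, 1), got {r2}")
    return float(np.std(signal) * np.sqrt((1.0 - r2) / r2))


def attach_trait_scores(
    cohort: CohortTable,
    ai_true: np.ndarray,
    trait_weights: np.ndarray,
    noise_sd: float | None = None,
    target_r2: float = 0.3,
    seed: int = 0,
    groups: tuple[str, ...] = ("autism",),
) -> CohortTable:
    """Couple ADOS scores to intra-hemispheric AI features.

    ``ai_true`` is the (subjects, pairs, k) AI array *without* site effects
    (the trait reflects the subject's true asymmetry, not scanner
    artifacts). ``trait_weights`` is a flat (pairs * k,) sparse vector.
    Total, communication, and social share the linear signal; RRB is pure
    noise. Scores are shifted/scaled to a plausible ADOS range, rounded,
    and clipped at 0. NaN outside ``groups``.
    """
    rng = np.random.default_rng(seed)
    X, _ = flatten_features(ai_true)
    w = np.asarray(trait_weights, dtype=float)
    if w.shape != (X.shape[1],):
        raise ParameterError(
            f"trait_weights shape {w.shape} does not match feature count {X.shape[1]}"
        )
    signal = X @ w
    if noise_sd is None:
        if np.std(signal) > 0:
            noise_sd = noise_sd_for_r2(signal, target_r2)
        else:
            noise_sd = 1.0
    latent = signal + noise_sd * rng.standard_normal(len(signal))

    def to_score(v: np.ndarray, mean: float, sd: float) -> np.ndarray:
        s = np.std(v)
        scaled = mean + (sd / s) * (v - np.mean(v)) if s > 0 else np.full_like(v, mean)
        return np.clip(np.round(scaled), 0, None)

    t = cohort.table.copy()
    mask = t["group"].isin(groups).to_numpy()
    total = to_score(latent, 12.0, 4.0)
    comm = to_score(0.5 * signal + noise_sd * rng.standard_normal(len(signal)), 4.0, 2.0)
    social = to_score(0.7 * signal + noise_sd * rng.standard_normal(len(signal)), 8.0, 3.0)
    rrb = to_score(rng.standard_normal(len(signal)), 3.0, 1.5)
    for col, vals in (
        ("ados_total", total), ("ados_comm", comm), ("ados_social", social), ("ados_rrb", rrb),
    ):
        v = np.full(len(t), np.nan)
        v[mask] = vals[mask]
        t[col] = v
    return CohortTable(t, matrices=cohort.matrices)


def make_trait_weights(
    n_pairs: int, k: int, causal: list[tuple[int, int]], weight: float = 1.0
) -> np.ndarray:
    """Sparse flat weight vector over (pair, gradient) intra features."""
    w = np.zeros(n_pairs * k)
    for pair, grad in causal:
        if not (0 <= pair < n_pairs and 0 <= grad < k):
            raise ParameterError(f"weight index ({pair}, {grad}) out of range")
        w[pair * k + grad] = weight
    return w


# ---------------------------------------------------------------------------
# meta-analytic term maps
# ---------------------------------------------------------------------------

def simulate_term_maps(
    n_terms: int,
    n_parcels: int = 180,
    seed: int = 0,
    planted_map: np.ndarray | None = None,
    term_names: list[str] | None = None,
) -> pd.DataFrame:
    """Synthetic per-term z-activation maps over one hemisphere's parcels.

    Stand-ins for meta-analytic cognitive-term maps: each term is a smooth
    random field. If ``planted_map`` is given, an extra term named
    'planted' equals its positive part, so a decoder must rank it first
    against the random terms.
    """
    if n_terms < 1:
        raise ParameterError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    base = _smooth_axes(n_parcels, min(n_parcels - 1, 8), rng)
    maps = {}
    names = term_names or [f"term{i:02d}" for i in range(n_terms)]
    for name in names[:n_terms]:
        coefs = rng.standard_normal(base.shape[1])
        m = base @ coefs + 0.3 * rng.standard_normal(n_parcels)
        maps[name] = m / np.std(m)
    if planted_map is not None:
        maps["planted"] = np.maximum(np.asarray(planted_map, dtype=float), 0.0)
    return pd.DataFrame(maps)
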