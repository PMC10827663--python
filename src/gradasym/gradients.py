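"""Connectome gradients: sparsification, affinity, diffusion-map embedding,
and Procrustes alignment to a template.

Each hemispheric block is row-sparsified to its strongest connections
(top 10% by default), converted to a normalized-angle cosine affinity
between connectivity profiles, and embedded with the anisotropic
diffusion map (alpha = 0.5). The trivial stationary component is
discarded and the next k eigenvectors become gradients G1..Gk, scaled by
the multiscale convention lambda/(1 - lambda) at diffusion time 0.
Individual gradient sets are rotated onto a group-level left-left
template with an orthogonal Procrustes rotation (no scaling, no
translation), which resolves sign and rotational indeterminacy and makes
subjects directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import PipelineConfig
from .connectome import HemiBlocks
from .errors import DegenerateDataError, DimensionError, ParameterError

BLOCK_SEED_HEMISPHERE = {"LL": "left", "LR": "left", "RL": "right", "RR": "right"}


@dataclass(frozen=True)
class GradientSet:
    """Eigenvectors (parcels x k) of one block's diffusion operator."""

    components: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    block_tag: str
    aligned: bool = False

    @property
    def seed_hemisphere(self) -> str:
        return BLOCK_SEED_HEMISPHERE[self.block_tag]

    @property
    def k(self) -> int:
        return self.components.shape[1]


@dataclass(frozen=True)
class GradientTemplate:
    """Reference gradients (group-level LL embedding) used as alignment target."""

    components: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[1]


def sparsify_rows(block: np.ndarray, density: float) -> np.ndarray:
    """Keep, per row, the top ``ceil(density * n)`` values; zero the rest.

    Retained values are unchanged. Ties at the cutoff break toward the
    lower column index (stable sort), so the output is deterministic.
    """
    if not (0.0 < density <= 1.0):
        raise ParameterError(f"density must be in (0, 1], got {density}")
    block = np.asarray(block, dtype=float)
    if not np.all(np.isfinite(block)):
        raise ParameterError("block contains non-finite entries")
    n = block.shape[1]
    m = int(np.ceil(density * n))
    if m >= n:
        return block.copy()
    out = np.zeros_like(block)
    # stable argsort of -row keeps the lowest column index first among ties
    order = np.argsort(-block, axis=1, kind="stable")[:, :m]
    rows = np.arange(block.shape[0])[:, None]
    out[rows, order] = block[rows, order]
    return out


def cosine_affinity(sparse_block: np.ndarray) -> np.ndarray:
    """Normalized-angle cosine affinity between sparsified row profiles.

    a_ij = 1 - arccos(clip(cos(x_i, x_j), -1, 1)) / pi, in [0, 1] with a
    unit diagonal. Identical rows give 1; orthogonal rows give 0.5.
    """
    x = np.asarray(sparse_block, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise DegenerateDataError(
            f"all-zero connectivity profile at row(s) {zero.tolist()[:10]}"
        )
    xn = x / norms[:, None]
    cos = np.clip(xn @ xn.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = np.maximum(aff, 0.0)
    np.fill_diagonal(aff, 1.0)
    # symmetrize away rounding asymmetry from the matmul
    return 0.5 * (aff + aff.T)


def _fix_column_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the entry of largest magnitude is positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def diffusion_embedding(
    affinity: np.ndarray,
    alpha: float = 0.5,
    k: int = 10,
    diffusion_time: float = 0.0,
    block_tag: str = "LL",
) -> GradientSet:
    """Anisotropic diffusion-map embedding of a symmetric affinity matrix.

    The affinity is density-normalized (W' = D^-alpha W D^-alpha), made
    row-stochastic, and eigendecomposed through its symmetric conjugate.
    The trivial stationary eigenvector is dropped; the next ``k``
    eigenvectors, in non-increasing eigenvalue order, are returned. At
    ``diffusion_time`` 0 components are scaled by lambda/(1 - lambda)
    (multiscale convention); a positive diffusion time scales by
    lambda**t; ``diffusion_time=None`` leaves them unscaled.

    ``variance_explained`` reports each retained eigenvalue's share of the
    total non-trivial spectrum magnitude.
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionError(f"affinity must be square, got {w.shape}")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ParameterError("affinity must be symmetric")
    if np.any(w < 0):
        raise ParameterError("affinity must be non-negative")
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than matrix size n={n}")
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")

    d = w.sum(axis=1)
    if np.any(d <= 0):
        raise DegenerateDataError("affinity has an isolated (zero-degree) node")
    d_alpha = d ** -alpha
    L = w * np.outer(d_alpha, d_alpha)
    d2 = L.sum(axis=1)
    # symmetric conjugate of the row-stochastic operator M = D2^-1 L
    inv_sqrt = 1.0 / np.sqrt(d2)
    S = L * np.outer(inv_sqrt, inv_sqrt)
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # right eigenvectors of M, unit-normalized, then scaled so the trivial
    # stationary column is the constant 1 (the standard convention)
    psi = evecs * inv_sqrt[:, None]
    psi = psi / np.linalg.norm(psi, axis=0)
    psi = psi / psi[:, [0]]
    lambdas = evals[1 : k + 1]
    comps = psi[:, 1 : k + 1]
    if diffusion_time is None:
        scale = np.ones_like(lambdas)
    elif diffusion_time == 0:
        scale = lambdas / (1.0 - np.clip(lambdas, None, 1.0 - 1e-12))
    else:
        scale = lambdas ** diffusion_time
    comps = _fix_column_signs(comps * scale)
    total = np.sum(np.abs(evals[1:]))
    var_exp = np.abs(lambdas) / total if total > 0 else np.zeros_like(lambdas)
    return GradientSet(
        components=comps,
        eigenvalues=lambdas,
        variance_explained=var_exp,
        block_tag=block_tag,
        aligned=False,
    )


def procrustes_rotation(source: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Orthogonal k x k rotation R minimizing ||source @ R - template||_F.

    No scaling, no translation. Computed from the SVD of
    source.T @ template; sign convention follows the SVD factors, which
    makes the solution deterministic also in the rank-deficient case.
    """
    source = np.asarray(source, dtype=float)
    template = np.asarray(template, dtype=float)
    if source.shape != template.shape:
        raise DimensionError(
            f"source {source.shape} and template {template.shape} must match"
        )
    if not (np.all(np.isfinite(source)) and np.all(np.isfinite(template))):
        raise ParameterError("inputs must be finite")
    u, _, vt = np.linalg.svd(source.T @ template)
    return u @ vt


def embed_block(
    block: np.ndarray,
    config: PipelineConfig,
    block_tag: str = "LL",
) -> GradientSet:
    """Sparsify -> affinity -> diffusion embedding for one hemispheric block."""
    sparse = sparsify_rows(block, config.sparsity_density)
    aff = cosine_affinity(sparse)
    return diffusion_embedding(
        aff,
        alpha=config.alpha,
        k=config.n_gradients_computed,
        diffusion_time=config.diffusion_time,
        block_tag=block_tag,
    )


def align_to_template(
    gset: GradientSet, template: GradientTemplate, normalize: bool = True
) -> GradientSet:
    """Rotate a gradient set onto the template in the full k-dimensional space.

    Components are column-normalized to unit length first (default): the
    per-component multiscale scaling is a global factor, and downstream
    analyses on aligned gradients are insensitive to it, while equalized
    column norms let the rotation weight all components evenly.
    """
    if gset.k != template.k:
        raise DimensionError(f"gradient k={gset.k} vs template k={template.k}")
    comps = gset.components
    if normalize:
        norms = np.linalg.norm(comps, axis=0)
        norms[norms == 0] = 1.0
        comps = comps / norms
    R = procrustes_rotation(comps, template.components)
    return replace(gset, components=comps @ R, aligned=True)


def align_subject(
    blocks: HemiBlocks, template: GradientTemplate, config: PipelineConfig
) -> dict[str, GradientSet]:
    """Embed all four blocks and rotate each onto the same LL template.

    Alignment happens in the full computed space (k = 10 by default); the
    first ``n_gradients_analyzed`` columns are read off downstream.
    """
    out: dict[str, GradientSet] = {}
    for tag, block in blocks.as_dict().items():
        gset = embed_block(block, config, block_tag=tag)
        out[tag] = align_to_template(gset, template)
    return out


def build_template(
    ll_blocks: list[np.ndarray] | np.ndarray, config: PipelineConfig
) -> GradientTemplate:
    """Group-level template: embedding of the subject-mean LL block.

    Averaging Fisher-z connectomes before embedding (not embedding then
    averaging) defines the group gradients.
    """
    if isinstance(ll_blocks, np.ndarray) and ll_blocks.ndim == 2:
        mean_ll = ll_blocks
    else:
        blocks = list(ll_blocks)
        if not blocks:
            raise ParameterError("cannot build a template from an empty cohort")
        mean_ll = np.mean(blocks, axis=0)
    gset = embed_block(mean_ll, config, block_tag="LL")
    return GradientTemplate(components=gset.components)
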