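"""Asymmetry indices, network aggregation, and inter-subject similarity.

The asymmetry index (AI) of a homolog pair is the left-hemisphere gradient
value minus the right-hemisphere value — deliberately non-normalized,
because gradient values take both signs and a (L-R)/(L+R) ratio would be
discontinuous. Positive AI = leftward dominance. The intra-hemispheric
pattern compares the LL and RR block gradients; the inter-hemispheric
pattern compares LR (left seeds over right targets) with RL (right seeds
over left targets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError
from .gradients import GradientSet
from .io_core import CohortTable, ParcellationScheme

PATTERNS = ("intra", "inter")


def asymmetry_index(gradient_left: np.ndarray, gradient_right: np.ndarray) -> np.ndarray:
    """AI = left - right, per homolog pair and gradient; positive = leftward."""
    left = np.asarray(gradient_left, dtype=float)
    right = np.asarray(gradient_right, dtype=float)
    if left.shape != right.shape:
        raise DimensionError(f"left {left.shape} vs right {right.shape}")
    return left - right


def subject_asymmetry(
    aligned: dict[str, GradientSet], n_gradients: int = 3
) -> dict[str, np.ndarray]:
    """Intra and inter AI maps (pairs x n_gradients) from four aligned blocks."""
    g = {tag: s.components[:, :n_gradients] for tag, s in aligned.items()}
    return {
        "intra": asymmetry_index(g["LL"], g["RR"]),
        "inter": asymmetry_index(g["LR"], g["RL"]),
    }


def network_mean(ai: np.ndarray, scheme: ParcellationScheme) -> pd.DataFrame:
    """Unweighted mean AI over each network's member pairs.

    Returns a (network x gradient) table, NaN (with a warning upstream)
    for a network with no pairs.
    """
    ai = np.asarray(ai, dtype=float)
    if ai.shape[0] != scheme.n_pairs:
        raise DimensionError(
            f"AI has {ai.shape[0]} pairs, parcellation has {scheme.n_pairs}"
        )
    nets = scheme.pair_networks
    rows = {}
    for net in scheme.networks:
        members = nets == net
        rows[net] = ai[members].mean(axis=0) if members.any() else np.full(ai.shape[1], np.nan)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = [f"G{j+1}" for j in range(ai.shape[1])]
    out.index.name = "network"
    return out


def stack_ai(ai_maps: list[np.ndarray]) -> np.ndarray:
    """Stack per-subject AI maps into (subjects, pairs, gradients)."""
    return np.stack([np.asarray(m, dtype=float) for m in ai_maps], axis=0)


def intersubject_similarity(
    ai_stack: np.ndarray,
    cohort: CohortTable,
    scope: str = "same_site",
) -> pd.DataFrame:
    """Idiosyncrasy score: each subject's mean Pearson correlation with peers.

    The AI maps (G1-G3 concatenated per subject) are correlated against
    every other subject in the reference population and averaged. Scope
    'same_site' (default) uses all same-site subjects regardless of group;
    'same_site_same_group' restricts to the subject's group; 'all' uses
    the whole cohort. Lower scores mean a more atypical, variable map.
    """
    if scope not in ("same_site", "same_site_same_group", "all"):
        raise ParameterError(f"unknown scope {scope!r}")
    X = np.asarray(ai_stack, dtype=float).reshape(ai_stack.shape[0], -1)
    t = cohort.table
    if len(t) != X.shape[0]:
        raise DimensionError("ai_stack and cohort have different subject counts")
    sd = X.std(axis=1)
    sites = np.asarray(t["site"])
    groups = np.asarray(t["group"])
    n = X.shape[0]
    # one pass of full correlations; cells are masked per scope below
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    corr = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    scores = np.full(n, np.nan)
    for i in range(n):
        if sd[i] == 0:
            continue  # undefined correlation; left missing
        if scope == "all":
            peers = np.ones(n, dtype=bool)
        else:
            peers = sites == sites[i]
            if scope == "same_site_same_group":
                peers &= groups == groups[i]
        peers[i] = False
        peers &= sd > 0
        if peers.sum() >= 2:
            scores[i] = corr[i, peers].mean()
    out = t[["subject_id", "group", "site"]].copy()
    out["similarity"] = scores
    return out
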