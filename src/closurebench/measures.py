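"""The two closure scores and their primitive similarities.

Similarity-based closure (triangle experiments)::

    Closure = cos(f(aligned), f(complete)) - cos(f(disordered), f(complete))

A positive value means the aligned (contour-continuing) figure is
represented more like the complete shape than the disordered one is —
the signature of perceptual completion.  For componentwise-nonnegative
activations the score lies in [-1, 1].

Configural-effect score (square experiments)::

    CE = (D(comp_c, comp_d) - D(base_c, base_d))
         / (D(comp_c, comp_d) + D(base_c, base_d))

with D the Euclidean distance between feature vectors.  CE > 0 means the
composite pair (parts plus identical closing context) is *more*
discriminable than the parts alone — a configural superiority effect.
By construction the stimulus sets make CE exactly 0 on raw pixels, so any
nonzero CE reflects the extractor's nonlinearity.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from . import exp1_stimuli, exp2_stimuli
from .features import extract


def _validate_pair(x, y, context: str = ""):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"feature vectors must be 1-D and of equal length{context}")
    return x, y


def cosine_similarity(x, y, ids: Optional[tuple] = None) -> float:
    context = f" ({ids[0]} vs {ids[1]})" if ids else ""
    x, y = _validate_pair(x, y, context)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        offender = (ids[0] if ids else "first vector") if nx == 0.0 else \
                   (ids[1] if ids else "second vector")
        raise ValueError(f"cosine similarity undefined for zero vector: {offender}")
    return float(np.dot(x, y) / (nx * ny))


def closure_measure(f_aligned, f_disordered, f_complete,
                    ids: Optional[dict] = None) -> float:
    ids = ids or {}
    return (
        cosine_similarity(f_aligned, f_complete,
                          (ids.get("aligned", "aligned"),
                           ids.get("complete", "complete")))
        - cosine_similarity(f_disordered, f_complete,
                            (ids.get("disordered", "disordered"),
                             ids.get("complete", "complete")))
    )


def euclidean_distance(x, y) -> float:
    x, y = _validate_pair(x, y)
    return float(np.linalg.norm(x - y))


def ce_measure(f_comp_c, f_comp_d, f_base_c, f_base_d,
               set_id: Optional[str] = None) -> float:
    d_comp = euclidean_distance(f_comp_c, f_comp_d)
    d_base = euclidean_distance(f_base_c, f_base_d)
    if d_comp + d_base == 0.0:
        raise ValueError(
            f"CE indeterminate (both pair distances zero)"
            f"{f' for set {set_id}' if set_id else ''}"
        )
    return (d_comp - d_base) / (d_comp + d_base)


# ---------------------------------------------------------------------------
# Scoring over full stimulus grids
# ---------------------------------------------------------------------------

CLOSURE_COLUMNS = ["variant", "theta_global", "edge_length", "theta_local",
                   "background", "center_x", "center_y", "value"]


def closure_records(features: Dict[exp1_stimuli.Exp1Params, np.ndarray]) -> pd.DataFrame:
    """Score every disordered figure against its aligned and complete matches.

    Each disordered image is paired with the aligned image sharing
    (theta_global, edge_length, background, center) and the complete image
    sharing (theta_global, background, center); the full grid yields one
    row per disordered figure (768 per variant), the granularity at which
    theta_local is defined.
    """
    aligned = {}
    complete = {}
    for p in features:
        if p.condition == "aligned":
            aligned[(p.variant, p.theta_global, p.edge_length,
                     p.background, p.center)] = p
        elif p.condition == "complete":
            complete[(p.variant, p.theta_global, p.background, p.center)] = p

    rows = []
    for p in features:
        if p.condition != "disordered":
            continue
        pa = aligned[(p.variant, p.theta_global, p.edge_length,
                      p.background, p.center)]
        pc = complete[(p.variant, p.theta_global, p.background, p.center)]
        value = closure_measure(
            features[pa], features[p], features[pc],
            ids={"aligned": exp1_stimuli.stimulus_filename(pa),
                 "disordered": exp1_stimuli.stimulus_filename(p),
                 "complete": exp1_stimuli.stimulus_filename(pc)})
        rows.append({
            "variant": p.variant,
            "theta_global": float(p.theta_global),
            "edge_length": float(p.edge_length),
            "theta_local": float(p.theta_local),
            "background": p.background,
            "center_x": float(p.center[0]),
            "center_y": float(p.center[1]),
            "value": value,
        })
    return pd.DataFrame(rows, columns=CLOSURE_COLUMNS)


def score_exp1(stimuli: Iterable[exp1_stimuli.StimulusImage],
               extractor) -> pd.DataFrame:
    """Extract features for a rendered grid and compute closure records."""
    features = {img.params: extract(img, extractor) for img in stimuli}
    return closure_records(features)


CE_COLUMNS = ["set_id", "condition", "theta_global", "edge_length",
              "background", "center_x", "center_y", "value"]


def ce_records(sets_features: List[tuple]) -> pd.DataFrame:
    """One CE row per set from (params, {role: vector}) pairs."""
    rows = []
    for p, vecs in sets_features:
        sid = exp2_stimuli.set_id(p)
        value = ce_measure(vecs["composite_c"], vecs["composite_d"],
                           vecs["base_c"], vecs["base_d"], set_id=sid)
        rows.append({
            "set_id": sid,
            "condition": p.condition,
            "theta_global": float(p.theta_global),
            "edge_length": float(p.edge_length),
            "background": p.background,
            "center_x": float(p.center[0]),
            "center_y": float(p.center[1]),
            "value": value,
        })
    return pd.DataFrame(rows, columns=CE_COLUMNS)


def score_exp2(pair_sets: Iterable[exp2_stimuli.PairSet],
               extractor) -> pd.DataFrame:
    sets_features = []
    for ps in pair_sets:
        vecs = {role: extract(img, extractor) for role, img in ps.images.items()}
        sets_features.append((ps.params, vecs))
    return ce_records(sets_features)
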