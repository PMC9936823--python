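"""Consumer-panel trait construction: score clipping and the MQ4 composite.

Each beef sample is tasted by a panel of 10 consumers who score it on a 0-100
scale. To damp extreme judgements the two highest and two lowest scores are
discarded and the remaining six averaged — the "clipped" sensory score. The
MQ4 eating-quality index is the fixed weighted sum

    MQ4 = 0.4*TENDER + 0.1*JUICY + 0.2*FLAVOR + 0.3*OVERALL.

The order of the two operations is ambiguous in practice (MQ4 could be formed
per consumer before clipping, or from the four clipped trait means); both are
provided via ``panel_traits(..., mq4_at_consumer_level=...)`` and the default
computes MQ4 from clipped trait scores.
"""

from __future__ import annotations

import numpy as np

PANEL_SIZE = 10
N_RETAINED = 6
MQ4_WEIGHTS = {"tender": 0.4, "juicy": 0.1, "flavor": 0.2, "overall": 0.3}


def clip_scores(scores) -> float:
    """Mean of the middle six order statistics of a 10-score consumer panel.

    Ties are resolved positionally: sort, drop positions 1-2 and 9-10.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (PANEL_SIZE,):
        raise ValueError(f"expected exactly {PANEL_SIZE} scores, got {scores.shape}")
    middle = np.sort(scores)[2:-2]
    return float(middle.mean())


def clip_scores_matrix(panels: np.ndarray) -> np.ndarray:
    """Vectorised :func:`clip_scores` over an (n_samples, 10) array."""
    panels = np.asarray(panels, dtype=float)
    if panels.shape[-1] != PANEL_SIZE:
        raise ValueError(f"last axis must have {PANEL_SIZE} consumer scores")
    return np.sort(panels, axis=-1)[..., 2:-2].mean(axis=-1)


def mq4(tender, juicy, flavor, overall):
    """MQ4 composite: 0.4*tender + 0.1*juicy + 0.2*flavor + 0.3*overall."""
    parts = (tender, juicy, flavor, overall)
    if not all(np.all(np.isfinite(p)) for p in parts):
        raise ValueError("MQ4 inputs must be finite")
    return 0.4 * np.asarray(tender) + 0.1 * np.asarray(juicy) \
        + 0.2 * np.asarray(flavor) + 0.3 * np.asarray(overall)


def panel_traits(panels: dict, mq4_at_consumer_level: bool = False) -> dict:
    """Clipped trait scores plus MQ4 from raw per-trait consumer panels.

    Parameters
    ----------
    panels
        Mapping of trait name -> (n_samples, 10) raw consumer scores for
        ``tender, juicy, flavor, overall``.
    mq4_at_consumer_level
        If True, form each consumer's MQ4 first and clip the resulting
        10-value MQ4 panel; otherwise (default) apply the MQ4 weights to the
        four clipped trait scores.
    """
    required = tuple(MQ4_WEIGHTS)
    missing = [t for t in required if t not in panels]
    if missing:
        raise KeyError(f"panels missing traits: {missing}")
    out = {t: clip_scores_matrix(np.asarray(panels[t])) for t in required}
    if mq4_at_consumer_level:
        per_consumer = sum(w * np.asarray(panels[t], dtype=float)
                           for t, w in MQ4_WEIGHTS.items())
        out["mq4"] = clip_scores_matrix(per_consumer)
    else:
        out["mq4"] = mq4(out["tender"], out["juicy"], out["flavor"], out["overall"])
    return out
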