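"""Semantic-consistent image-translation objectives as pure array functions.

These are the training objectives of an unpaired endoscopy-to-render style
translator: cycle consistency, the two-direction adversarial term, and a
semantic (K-way cross-entropy) consistency term that penalises translators
that hallucinate or erase anatomical holes. No networks are trained here —
the functions operate on arbitrary callables and small arrays so the
objective itself is testable.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

_CLAMP = 1e-7


def _batch(x) -> np.ndarray:
    arr = np.asarray(x, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("batch contains non-finite values")
    return arr


def cycle_loss(g_st, g_ts, batch_s, batch_t) -> float:
    """Two-direction mean-absolute cycle reconstruction error.

    ``E||g_ts(g_st(s)) - s||_1 + E||g_st(g_ts(t)) - t||_1`` with the
    expectation an arithmetic mean over batch elements and pixels.
    """
    bs = _batch(batch_s)
    bt = _batch(batch_t)
    rec_s = _batch(g_ts(g_st(bs)))
    rec_t = _batch(g_st(g_ts(bt)))
    if rec_s.shape != bs.shape or rec_t.shape != bt.shape:
        raise ValueError("generators must preserve batch shape")
    return float(np.mean(np.abs(rec_s - bs)) + np.mean(np.abs(rec_t - bt)))


def adversarial_loss(g_st, d_t, batch_s, batch_t) -> float:
    """One-direction GAN value: E[ln D(real)] + E[ln(1 - D(fake))].

    Discriminator outputs are clamped to [1e-7, 1 - 1e-7] (with a log
    message) so the value stays finite at the saturated limits.
    """
    real = np.asarray(d_t(_batch(batch_t)), float)
    fake = np.asarray(d_t(_batch(g_st(_batch(batch_s)))), float)
    if np.any(real <= 0) or np.any(real >= 1) or np.any(fake <= 0) or np.any(fake >= 1):
        log.info("discriminator output clamped to (0, 1)")
    real = np.clip(real, _CLAMP, 1 - _CLAMP)
    fake = np.clip(fake, _CLAMP, 1 - _CLAMP)
    return float(np.mean(np.log(real)) + np.mean(np.log(1.0 - fake)))


def symmetric_adversarial_loss(g_st, g_ts, d_t, d_s, batch_s, batch_t) -> float:
    """Both translation directions' adversarial values summed."""
    return adversarial_loss(g_st, d_t, batch_s, batch_t) \
        + adversarial_loss(g_ts, d_s, batch_t, batch_s)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def semantic_task_loss(u_s, g, batch, reference_masks) -> float:
    """Mean per-pixel K-way cross-entropy of the segmenter on translated images.

    ``u_s`` maps an image batch to (..., H, W, K) logits; ``reference_masks``
    holds per-pixel labels in {1..K} (known exactly for synthetic scenes).
    """
    logits = np.asarray(u_s(g(_batch(batch))), float)
    labels = np.asarray(reference_masks, int)
    k = logits.shape[-1]
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    probs = _softmax(logits)
    picked = np.take_along_axis(probs, (labels - 1)[..., None], axis=-1)[..., 0]
    return float(-np.mean(np.log(np.clip(picked, _CLAMP, None))))


def semantic_consistency_loss(u_s, g_st, g_ts, batch_s, batch_t,
                              masks_s, masks_t) -> float:
    """Semantic term summed over both translation directions."""
    return semantic_task_loss(u_s, g_st, batch_s, masks_s) \
        + semantic_task_loss(u_s, g_ts, batch_t, masks_t)


def total_loss(l_cyc: float, l_gan: float, l_sem: float) -> float:
    """Full objective: (cycle + adversarial) base plus the semantic term."""
    parts = (l_cyc, l_gan, l_sem)
    if not all(np.isfinite(parts)):
        raise ValueError("all loss components must be finite")
    return float(l_cyc + l_gan + l_sem)
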