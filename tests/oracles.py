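"""Naive, definition-level reference implementations used as test oracles.

Everything here is written directly from the definitions (explicit loops,
plain window means, ``scipy.stats.pearsonr``) and shares no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr


def brute_match_profile(bases: str, residues: str, scale_values: dict,
                        base_set: set, w: int = 21) -> dict[int, float]:
    """Sliding Pearson profile by per-fragment recomputation.

    Returns a map from 1-based genome position to R (NaN for zero-variance
    windows), including the even-length centre-averaging rule.
    """
    L, n, h = len(bases), len(residues), (w - 1) // 2
    track = np.array([sum(b in base_set for b in bases[i:i + 3]) / 3
                      for i in range(L - 2)])
    vals = np.array([scale_values[r] for r in residues])
    prot = np.array([vals[j - h:j + h + 1].mean() for j in range(h, n - h)])
    l = len(prot)

    def smoothed_density(t: int) -> float:  # t: 0-based triplet index
        return track[[t + 3 * k for k in range(-h, h + 1)]].mean()

    frag: dict[int, float] = {}
    t_lo, t_hi = 3 * h, (L - 3) - 3 * h
    q = t_lo
    while q + 3 * (l - 1) <= t_hi:
        x = np.array([smoothed_density(q + 3 * k) for k in range(l)])
        # tracks are quantized in 1/63 steps, so anything below 1e-9 is a
        # constant window up to summation rounding
        if x.std() < 1e-9 or prot.std() < 1e-9:
            frag[q] = float("nan")
        else:
            frag[q] = float(pearsonr(x, prot).statistic)
        q += 1

    span = 3 * l
    out: dict[int, float] = {}
    if span % 2 == 1:
        for q, r in frag.items():
            out[q + 1 + (span - 1) // 2] = r
    else:
        qs = sorted(frag)
        for a, b in zip(qs[:-1], qs[1:]):
            out[a + 1 + span // 2] = 0.5 * (frag[a] + frag[b])
    return out


def brute_energy_profile(bases: str, residues: str, scales: dict,
                         sw: int = 63) -> dict[str, dict[int, float]]:
    """Energy profile by per-fragment, per-triplet recomputation.

    ``scales`` maps each base A/G/C/U to a residue->affinity dict.  Returns
    ``{"raw": {...}, "smoothed": {...}, "z": {...}}`` keyed by 1-based
    genome position.
    """
    L, n = len(bases), len(residues)
    span = 3 * n
    frag = []
    for p0 in range(L - span + 1):  # 0-based fragment start
        e = 0.0
        for j, aa in enumerate(residues):
            triplet = bases[p0 + 3 * j: p0 + 3 * j + 3]
            for b in "AGCU":
                e += scales[b][aa] * triplet.count(b)
        frag.append(e)
    frag = np.array(frag)

    raw: dict[int, float] = {}
    if span % 2 == 1:
        for p0, e in enumerate(frag):
            raw[p0 + 1 + (span - 1) // 2] = float(e)
    else:
        for p0 in range(len(frag) - 1):
            raw[p0 + 1 + span // 2] = float(0.5 * (frag[p0] + frag[p0 + 1]))

    pos_sorted = sorted(raw)
    half = (sw - 1) // 2
    smoothed: dict[int, float] = {}
    for i in range(half, len(pos_sorted) - half):
        window = [raw[pos_sorted[i + k]] for k in range(-half, half + 1)]
        smoothed[pos_sorted[i]] = float(np.mean(window))
    sm_vals = np.array([smoothed[p] for p in sorted(smoothed)])
    mean, sd = sm_vals.mean(), sm_vals.std(ddof=0)
    z = {p: float((v - mean) / sd) if sd > 0 else float("nan")
         for p, v in smoothed.items()}
    return {"raw": raw, "smoothed": smoothed, "z": z}
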