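"""Numba kernels for the per-frame image operations.

Full-length recordings put tens of thousands of frames through the median
filter and edge detector, so both are implemented as compiled kernels:

* ``median_u8`` — 2-D median with a sliding histogram (Huang's algorithm),
  exact for 8-bit data.  Matches ``scipy.ndimage.median_filter`` with
  ``mode='nearest'`` bit for bit (the border is edge-replicated by padding
  before the call).
* ``nms_hysteresis`` — gradient-direction non-maximum suppression followed
  by stack-based hysteresis tracking, the second half of the Canny detector.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def median_u8(padded: np.ndarray, mh: int, nh: int, out: np.ndarray) -> None:
    """Sliding-histogram median of an edge-padded uint8 image.

    ``padded`` must be the source padded by ``mh//2`` rows and ``nh//2``
    columns on each side; the ``(H, W)`` result is written into ``out``.
    """
    H, W = out.shape
    half = (mh * nh) // 2  # median = smallest m with count(<= m) > half
    hist = np.zeros(256, np.int32)
    for i in range(H):
        hist[:] = 0
        for a in range(mh):
            for b in range(nh):
                hist[padded[i + a, b]] += 1
        cnt = 0
        mdn = 0
        while True:
            cnt += hist[mdn]
            if cnt > half:
                break
            mdn += 1
        ltm = cnt - hist[mdn]  # values strictly below the running median
        out[i, 0] = mdn
        for j in range(1, W):
            for a in range(mh):
                v = padded[i + a, j - 1]
                hist[v] -= 1
                if v < mdn:
                    ltm -= 1
                v = padded[i + a, j + nh - 1]
                hist[v] += 1
                if v < mdn:
                    ltm += 1
            while ltm > half:
                mdn -= 1
                ltm -= hist[mdn]
            while ltm + hist[mdn] <= half:
                ltm += hist[mdn]
                mdn += 1
            out[i, j] = mdn


@njit(cache=True, fastmath=True)
def gaussian_gradients_2d(
    padded: np.ndarray,
    k_smooth: np.ndarray,
    k_deriv: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    mag: np.ndarray,
) -> None:
    """Separable Gaussian-derivative gradients of one channel.

    ``padded`` is the ``(M, N)`` channel edge-padded by the kernel radius
    on every side; ``k_smooth``/``k_deriv`` are the sampled Gaussian and
    its derivative (odd length).  Writes the row-derivative into ``gx``,
    the column-derivative into ``gy`` and the magnitude into ``mag``.
    Loops are ordered so the innermost axis is contiguous (vectorizable).
    """
    M, N = gx.shape
    K = k_smooth.size
    NP = padded.shape[1]
    s0 = np.zeros((M, NP), np.float32)  # smoothed along rows
    d0 = np.zeros((M, NP), np.float32)  # differentiated along rows
    for k in range(K):
        cs = k_smooth[k]
        cd = k_deriv[k]
        for i in range(M):
            row = padded[i + k]
            for j in range(NP):
                v = row[j]
                s0[i, j] += cs * v
                d0[i, j] += cd * v
    for i in range(M):
        for j in range(N):
            gx[i, j] = 0.0
            gy[i, j] = 0.0
    for k in range(K):
        cs = k_smooth[k]
        cd = k_deriv[k]
        for i in range(M):
            for j in range(N):
                gx[i, j] += cs * d0[i, j + k]
                gy[i, j] += cd * s0[i, j + k]
    for i in range(M):
        for j in range(N):
            mag[i, j] = np.sqrt(gx[i, j] * gx[i, j] + gy[i, j] * gy[i, j])


@njit(cache=True)
def nms_hysteresis(
    mag: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    high: float,
    low: float,
    out: np.ndarray,
) -> None:
    """Canny back end for one channel: thin ridges, then track by hysteresis.

    ``mag``/``gx``/``gy`` are the gradient magnitude and components
    (``gx`` = derivative along rows, ``gy`` = along columns).  A pixel
    survives non-maximum suppression when its magnitude is at least that of
    both neighbours along the quantized gradient direction; surviving pixels
    above ``high`` seed a flood fill over surviving pixels above ``low``.
    """
    H, W = mag.shape
    TAN225 = 0.41421356237309503  # tan(22.5 deg)
    # 0: gradient ~ row axis, 1: diag, 2: ~ column axis, 3: anti-diag
    strong_r = np.empty(H * W, np.int32)
    strong_c = np.empty(H * W, np.int32)
    n_strong = 0
    cand = np.zeros((H, W), np.uint8)
    for i in range(1, H - 1):
        for j in range(1, W - 1):
            m = mag[i, j]
            if m <= low:
                continue
            ax = abs(gx[i, j])
            ay = abs(gy[i, j])
            same_sign = (gx[i, j] >= 0) == (gy[i, j] >= 0)
            if ay <= TAN225 * ax:  # gradient along rows -> compare row neighbours
                a = mag[i - 1, j]
                b = mag[i + 1, j]
            elif ax <= TAN225 * ay:  # gradient along columns
                a = mag[i, j - 1]
                b = mag[i, j + 1]
            elif same_sign:  # diagonal
                a = mag[i - 1, j - 1]
                b = mag[i + 1, j + 1]
            else:  # anti-diagonal
                a = mag[i - 1, j + 1]
                b = mag[i + 1, j - 1]
            if m >= a and m >= b:
                cand[i, j] = 1
                if m > high:
                    strong_r[n_strong] = i
                    strong_c[n_strong] = j
                    n_strong += 1
    # flood fill (8-connectivity) from strong pixels over candidates
    stack_r = np.empty(H * W, np.int32)
    stack_c = np.empty(H * W, np.int32)
    for k in range(n_strong):
        i0 = strong_r[k]
        j0 = strong_c[k]
        if out[i0, j0]:
            continue
        out[i0, j0] = True
        top = 0
        stack_r[top] = i0
        stack_c[top] = j0
        top += 1
        while top > 0:
            top -= 1
            i = stack_r[top]
            j = stack_c[top]
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    ii = i + di
                    jj = j + dj
                    if 0 <= ii < H and 0 <= jj < W:
                        if cand[ii, jj] and not out[ii, jj]:
                            out[ii, jj] = True
                            stack_r[top] = ii
                            stack_c[top] = jj
                            top += 1
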