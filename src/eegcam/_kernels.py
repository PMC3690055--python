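"""Numba-compiled image kernels: Sobel, Shi-Tomasi corners, pyramidal LK.

All kernels work on float32 images in native 8-bit intensity units (0..255)
with replicate borders.  They are shared by the per-frame-pair public API in
:mod:`eegcam.video` and by the batched per-trial feature path, so both
routes are arithmetically identical.  Interior pixels are computed in tight
SIMD-friendly loops; borders are handled separately with clamped indexing.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def sobel_gradients(img):
    """Horizontal/vertical 3x3 Sobel responses with replicate padding."""
    h, w = img.shape
    gx = np.empty((h, w), np.float32)
    gy = np.empty((h, w), np.float32)
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            a = img[y - 1, x - 1]
            b = img[y - 1, x]
            c = img[y - 1, x + 1]
            d = img[y, x - 1]
            f = img[y, x + 1]
            g = img[y + 1, x - 1]
            hh = img[y + 1, x]
            i = img[y + 1, x + 1]
            gx[y, x] = (c + 2.0 * f + i) - (a + 2.0 * d + g)
            gy[y, x] = (g + 2.0 * hh + i) - (a + 2.0 * b + c)
    # borders: replicate padding via clamped indices
    for y in range(h):
        inner_y = y != 0 and y != h - 1
        for x in range(w):
            if inner_y and x != 0 and x != w - 1:
                continue
            ym = max(y - 1, 0)
            yp = min(y + 1, h - 1)
            xm = max(x - 1, 0)
            xp = min(x + 1, w - 1)
            a = img[ym, xm]
            b = img[ym, x]
            c = img[ym, xp]
            d = img[y, xm]
            f = img[y, xp]
            g = img[yp, xm]
            hh = img[yp, x]
            i = img[yp, xp]
            gx[y, x] = (c + 2.0 * f + i) - (a + 2.0 * d + g)
            gy[y, x] = (g + 2.0 * hh + i) - (a + 2.0 * b + c)
    return gx, gy


@njit(cache=True, fastmath=True)
def sobel_magnitude_map(img):
    """L2 combination of the two 3x3 Sobel mask responses."""
    gx, gy = sobel_gradients(img)
    h, w = img.shape
    mag = np.empty((h, w), np.float32)
    for y in range(h):
        for x in range(w):
            mag[y, x] = np.sqrt(gx[y, x] * gx[y, x] + gy[y, x] * gy[y, x])
    return mag


@njit(cache=True, fastmath=True)
def mean_abs_diff(a, b):
    """Mean absolute per-pixel difference of two same-shape images."""
    h, w = a.shape
    s = 0.0
    for y in range(h):
        rs = np.float32(0.0)
        for x in range(w):
            rs += abs(a[y, x] - b[y, x])
        s += rs
    return s / (h * w)


@njit(cache=True, fastmath=True)
def _box_sum(img, radius):
    """Separable (2r+1)-box sum with replicate borders (running window)."""
    h, w = img.shape
    tmp = np.empty((h, w), np.float32)
    out = np.empty((h, w), np.float32)
    for y in range(h):
        s = np.float32(0.0)
        for k in range(-radius, radius + 1):
            s += img[y, min(max(k, 0), w - 1)]
        tmp[y, 0] = s
        for x in range(1, w):
            s += img[y, min(x + radius, w - 1)] - img[y, max(x - radius - 1, 0)]
            tmp[y, x] = s
    for x in range(w):
        s = np.float32(0.0)
        for k in range(-radius, radius + 1):
            s += tmp[min(max(k, 0), h - 1), x]
        out[0, x] = s
    for y in range(1, h):
        yp = min(y + radius, h - 1)
        ym = max(y - radius - 1, 0)
        for x in range(w):
            out[y, x] = out[y - 1, x] + tmp[yp, x] - tmp[ym, x]
    return out


@njit(cache=True, fastmath=True)
def corner_response(img, block_radius):
    """Shi-Tomasi response: min eigenvalue of the windowed structure tensor.

    Gradients are Sobel responses scaled by 1/8 (the mask's derivative gain),
    summed over a (2r+1)^2 box.
    """
    gx, gy = sobel_gradients(img)
    h, w = img.shape
    xx = np.empty((h, w), np.float32)
    yy = np.empty((h, w), np.float32)
    xy = np.empty((h, w), np.float32)
    for y in range(h):
        for x in range(w):
            fx = gx[y, x] * np.float32(0.125)
            fy = gy[y, x] * np.float32(0.125)
            xx[y, x] = fx * fx
            yy[y, x] = fy * fy
            xy[y, x] = fx * fy
    sxx = _box_sum(xx, block_radius)
    syy = _box_sum(yy, block_radius)
    sxy = _box_sum(xy, block_radius)
    resp = np.empty((h, w), np.float32)
    for y in range(h):
        for x in range(w):
            tr = sxx[y, x] + syy[y, x]
            dif = sxx[y, x] - syy[y, x]
            disc = np.sqrt(dif * dif + 4.0 * sxy[y, x] * sxy[y, x])
            resp[y, x] = 0.5 * (tr - disc)
    return resp


@njit(cache=True)
def select_corners(resp, max_corners, quality, min_distance, border):
    """Greedy quality-thresholded corner picking with 3x3 NMS.

    Returns an (n, 2) float32 array of (x, y) positions sorted by descending
    response, enforcing a minimum pairwise distance.
    """
    h, w = resp.shape
    rmax = np.float32(0.0)
    for y in range(border, h - border):
        for x in range(border, w - border):
            if resp[y, x] > rmax:
                rmax = resp[y, x]
    out = np.empty((max_corners, 2), np.float32)
    if rmax <= 0:
        return out[:0]
    thr = quality * rmax
    cand_y = []
    cand_x = []
    cand_r = []
    for y in range(border, h - border):
        for x in range(border, w - border):
            v = resp[y, x]
            if v < thr:
                continue
            is_max = True
            for dy in range(-1, 2):
                for dx in range(-1, 2):
                    if resp[y + dy, x + dx] > v:
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max:
                cand_y.append(y)
                cand_x.append(x)
                cand_r.append(v)
    n = len(cand_r)
    order = np.argsort(np.array(cand_r))[::-1]
    mind2 = min_distance * min_distance
    count = 0
    for idx in range(n):
        i = order[idx]
        px = np.float32(cand_x[i])
        py = np.float32(cand_y[i])
        ok = True
        for j in range(count):
            dx = out[j, 0] - px
            dy = out[j, 1] - py
            if dx * dx + dy * dy < mind2:
                ok = False
                break
        if ok:
            out[count, 0] = px
            out[count, 1] = py
            count += 1
            if count >= max_corners:
                break
    return out[:count].copy()


@njit(cache=True, fastmath=True)
def pyr_down(img):
    """Halve an image with a 5-tap binomial blur (replicate borders)."""
    h, w = img.shape
    h2 = (h + 1) // 2
    w2 = (w + 1) // 2
    tmp = np.empty((h, w2), np.float32)
    for y in range(h):
        for x2 in range(w2):
            x = 2 * x2
            xm2 = max(x - 2, 0)
            xm1 = max(x - 1, 0)
            xp1 = min(x + 1, w - 1)
            xp2 = min(x + 2, w - 1)
            tmp[y, x2] = (img[y, xm2] + 4.0 * img[y, xm1] + 6.0 * img[y, x]
                          + 4.0 * img[y, xp1] + img[y, xp2]) / 16.0
    out = np.empty((h2, w2), np.float32)
    for y2 in range(h2):
        y = 2 * y2
        ym2 = max(y - 2, 0)
        ym1 = max(y - 1, 0)
        yp1 = min(y + 1, h - 1)
        yp2 = min(y + 2, h - 1)
        for x2 in range(w2):
            out[y2, x2] = (tmp[ym2, x2] + 4.0 * tmp[ym1, x2] + 6.0 * tmp[y, x2]
                           + 4.0 * tmp[yp1, x2] + tmp[yp2, x2]) / 16.0
    return out


@njit(cache=True, fastmath=True, inline="always")
def _bilinear(img, x, y):
    x0 = int(np.floor(x))
    y0 = int(np.floor(y))
    ax = x - x0
    ay = y - y0
    return ((1.0 - ax) * (1.0 - ay) * img[y0, x0]
            + ax * (1.0 - ay) * img[y0, x0 + 1]
            + (1.0 - ax) * ay * img[y0 + 1, x0]
            + ax * ay * img[y0 + 1, x0 + 1])


@njit(cache=True, fastmath=True)
def lk_level(img_a, img_b, pts, guesses, half_win, max_iter, eps, min_eig):
    """One pyramid level of iterative Lucas-Kanade for all points.

    ``pts`` are (x, y) template centers in ``img_a`` at this level's scale;
    ``guesses`` are the incoming displacement estimates.  A point fails
    (status 0) if its window leaves the image or the spatial-gradient matrix
    is degenerate (per-pixel min eigenvalue below ``min_eig``).
    """
    h, w = img_a.shape
    n = pts.shape[0]
    win = 2 * half_win + 1
    area = win * win
    out = np.empty((n, 2), np.float32)
    status = np.ones(n, np.uint8)
    pad = win + 2
    patch = np.empty((pad, pad), np.float32)
    ta = np.empty((win, win), np.float32)
    gxp = np.empty((win, win), np.float32)
    gyp = np.empty((win, win), np.float32)
    tb = np.empty((win, win), np.float32)
    for i in range(n):
        px = pts[i, 0]
        py = pts[i, 1]
        if (px - half_win < 2.0 or px + half_win > w - 4.0
                or py - half_win < 2.0 or py + half_win > h - 4.0):
            status[i] = 0
            out[i, 0] = guesses[i, 0]
            out[i, 1] = guesses[i, 1]
            continue
        # padded template patch; gradients by central differences inside it
        for r in range(pad):
            yy = py + (r - half_win - 1)
            for c in range(pad):
                patch[r, c] = _bilinear(img_a, px + (c - half_win - 1), yy)
        gxx = 0.0
        gyy = 0.0
        gxy = 0.0
        for r in range(win):
            for c in range(win):
                ta[r, c] = patch[r + 1, c + 1]
                dx = 0.5 * (patch[r + 1, c + 2] - patch[r + 1, c])
                dy = 0.5 * (patch[r + 2, c + 1] - patch[r, c + 1])
                gxp[r, c] = dx
                gyp[r, c] = dy
                gxx += dx * dx
                gyy += dy * dy
                gxy += dx * dy
        tr = gxx + gyy
        det = gxx * gyy - gxy * gxy
        mineig = 0.5 * (tr - np.sqrt(max(tr * tr - 4.0 * det, 0.0))) / area
        if mineig < min_eig or det <= 0.0:
            status[i] = 0
            out[i, 0] = guesses[i, 0]
            out[i, 1] = guesses[i, 1]
            continue
        dxv = guesses[i, 0]
        dyv = guesses[i, 1]
        ok = True
        for _ in range(max_iter):
            cx = px + dxv
            cy = py + dyv
            if (cx - half_win < 1.0 or cx + half_win > w - 3.0
                    or cy - half_win < 1.0 or cy + half_win > h - 3.0):
                ok = False
                break
            b0 = 0.0
            b1 = 0.0
            for r in range(win):
                yy = cy + (r - half_win)
                for c in range(win):
                    diff = ta[r, c] - _bilinear(img_b, cx + (c - half_win), yy)
                    b0 += gxp[r, c] * diff
                    b1 += gyp[r, c] * diff
            ddx = (gyy * b0 - gxy * b1) / det
            ddy = (gxx * b1 - gxy * b0) / det
            dxv += ddx
            dyv += ddy
            if ddx * ddx + ddy * ddy < eps * eps:
                break
        if not ok:
            status[i] = 0
        out[i, 0] = dxv
        out[i, 1] = dyv
    return out, status


@njit(cache=True)
def _build_pyramid(img, levels):
    pyr = [img]
    for _ in range(levels - 1):
        last = pyr[-1]
        if last.shape[0] < 16 or last.shape[1] < 16:
            break
        pyr.append(pyr_down(last))
    return pyr


@njit(cache=True)
def track_pyramidal(pyr_a, pyr_b, pts, half_win, max_iter, eps, min_eig):
    """Coarse-to-fine LK over two pyramids; returns (displacements, status)."""
    n = pts.shape[0]
    disp = np.zeros((n, 2), np.float32)
    status = np.ones(n, np.uint8)
    nlev = min(len(pyr_a), len(pyr_b))
    for lev in range(nlev - 1, -1, -1):
        scale = np.float32(2.0 ** lev)
        lpts = (pts / scale).astype(np.float32)
        disp, st = lk_level(pyr_a[lev], pyr_b[lev], lpts, disp,
                            half_win, max_iter, eps, min_eig)
        for i in range(n):
            status[i] &= st[i]
        if lev > 0:
            for i in range(n):
                disp[i, 0] *= np.float32(2.0)
                disp[i, 1] *= np.float32(2.0)
    return disp, status


@njit(cache=True)
def image_features_stack(stack, max_corners, quality, min_distance, window,
                         levels, max_iter, eps, min_eig, block_radius, min_mag):
    """Four motion features for every consecutive pair of a uint8 frame stack.

    Single-pass driver reusing each frame's Sobel map and pyramid across
    adjacent pairs; composes exactly the same kernels as the per-pair API.
    Returns (n_frames - 1, 4): pixel_diff, edge_diff, mv_avg_mag, mv_count.
    """
    nf = stack.shape[0]
    out = np.zeros((nf - 1, 4))
    half = window // 2
    border = max(half + 2, block_radius + 1)
    prev = stack[0].astype(np.float32)
    prev_sob = sobel_magnitude_map(prev)
    prev_pyr = _build_pyramid(prev, levels)
    for i in range(1, nf):
        cur = stack[i].astype(np.float32)
        cur_sob = sobel_magnitude_map(cur)
        cur_pyr = _build_pyramid(cur, levels)
        pdiff = mean_abs_diff(prev, cur)
        ediff = mean_abs_diff(prev_sob, cur_sob)
        resp = corner_response(prev, block_radius)
        pts = select_corners(resp, max_corners, quality, min_distance, border)
        avg_mag = 0.0
        count = 0
        if pts.shape[0] > 0:
            disp, status = track_pyramidal(prev_pyr, cur_pyr, pts,
                                           half, max_iter, eps, min_eig)
            s = 0.0
            for j in range(pts.shape[0]):
                if status[j]:
                    mag = np.sqrt(disp[j, 0] * disp[j, 0]
                                  + disp[j, 1] * disp[j, 1])
                    if mag >= min_mag:
                        s += mag
                        count += 1
            if count > 0:
                avg_mag = s / count
        out[i - 1, 0] = pdiff
        out[i - 1, 1] = ediff
        out[i - 1, 2] = avg_mag
        out[i - 1, 3] = count
        prev = cur
        prev_sob = cur_sob
        prev_pyr = cur_pyr
    return out


@njit(cache=True, fastmath=True)
def render_crops(texture, xs, ys, x0, y0, height, width):
    """Render uint8 frames by bilinearly cropping ``texture`` at subpixel
    offsets (x0 + xs[i], y0 + ys[i]); used by the synthetic-scene generator."""
    n = xs.shape[0]
    out = np.empty((n, height, width), np.uint8)
    th, tw = texture.shape
    for i in range(n):
        ox = x0 + xs[i]
        oy = y0 + ys[i]
        ix = int(np.floor(ox))
        iy = int(np.floor(oy))
        ax = np.float32(ox - ix)
        ay = np.float32(oy - iy)
        w00 = (1.0 - ax) * (1.0 - ay)
        w10 = ax * (1.0 - ay)
        w01 = (1.0 - ax) * ay
        w11 = ax * ay
        for r in range(height):
            ty = iy + r
            for c in range(width):
                tx = ix + c
                v = (w00 * texture[ty, tx] + w10 * texture[ty, tx + 1]
                     + w01 * texture[ty + 1, tx] + w11 * texture[ty + 1, tx + 1])
                iv = int(v + 0.5)
                if iv > 255:
                    iv = 255
                elif iv < 0:
                    iv = 0
                out[i, r, c] = np.uint8(iv)
    return out
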