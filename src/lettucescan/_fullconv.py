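"""Fully-convolutional sliding-window scoring.

Scoring every stride-5 window of a tile independently recomputes each
convolution up to 16 times, and on ordinary hardware the im2col traffic —
not the arithmetic — dominates.  Because all convolutions are stride-1, the
conv blocks can instead be run once over the whole tile and each window's
5x5x64 feature block read out of the shared maps; only the dense head is
evaluated per window.  The 2x2 poolings introduce a phase: a window starting
at an odd row pools different row pairs than one starting at an even row, so
both phases of each pooling (16 combinations over two pools and two axes) are
kept and every lattice window reads from the map matching its offset.

One semantic difference from patch-wise inference: inside the tile a window's
conv features see the true neighbouring pixels where an isolated 20x20 patch
would see zero padding.  The affected band is the outer two pixels of the
window; head probabilities are dominated by the interior and the detection
pipeline's candidate sets are unchanged in practice (asserted against the
patch-wise path in the test suite).

Conv blocks run in horizontal strips (with a 2-row halo, exactly the receptive
field of two 3x3 convolutions) so that the im2col buffers stay cache-sized.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _nn

_STRIP = 40          # strip height in rows; keeps conv2 im2col ~<12 MB
_HALO = 2            # receptive-field radius of two stacked 3x3 convs
_HEAD_CHUNK = 4096


def _run_conv_block(layers, x: np.ndarray) -> np.ndarray:
    """Apply conv/BN/ReLU layers to an (H, W, C) map, strip by strip."""
    h = x.shape[0]
    outs = []
    for y0 in range(0, h, _STRIP):
        y1 = min(y0 + _STRIP, h)
        a, b = max(y0 - _HALO, 0), min(y1 + _HALO, h)
        s = x[a:b][None]
        for layer in layers:
            s = layer.forward(s, False, None)
        outs.append(s[0][y0 - a: y0 - a + (y1 - y0)])
    return np.concatenate(outs) if len(outs) > 1 else outs[0]


def _pool_phase(m: np.ndarray, py: int, px: int) -> np.ndarray:
    """2x2 max pool of an (H, W, C) map starting at row/col phase (py, px)."""
    sub = m[py:, px:, :]
    h2 = sub.shape[0] // 2 * 2
    w2 = sub.shape[1] // 2 * 2
    return sub[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2, -1).max(axis=(1, 3))


def _split_blocks(net: _nn.Network):
    """Partition the fixed architecture into conv blocks and the dense head."""
    layers = net.layers
    pools = [i for i, l in enumerate(layers) if isinstance(l, _nn.MaxPool2)]
    flat = next(i for i, l in enumerate(layers) if isinstance(l, _nn.Flatten))
    block1 = layers[: pools[0]]
    block2 = layers[pools[0] + 1: pools[1]]
    dense = [l for l in layers[flat + 1:] if isinstance(l, _nn.Dense)]
    return block1, block2, dense


def lattice_probabilities(net: _nn.Network, tile: np.ndarray,
                          stride: int = 5, window: int = 20) -> np.ndarray:
    """Head probabilities for every stride-lattice window of a grey tile.

    Returns an ``(ny, nx)`` array where entry ``(iy, ix)`` is the probability
    for the window whose top-left corner is ``(ix*stride, iy*stride)``.
    """
    th, tw = tile.shape
    if th < window or tw < window:
        raise ValueError("tile smaller than the sliding window")
    block1, block2, (dense1, dense2) = _split_blocks(net)

    x = (np.asarray(tile, dtype=_nn.F32) / _nn.F32(255.0))[:, :, None]
    f1 = _run_conv_block(block1, x)

    # quarter-resolution feature maps for every pooling-phase combination
    maps: dict[tuple[int, int, int, int], np.ndarray] = {}
    for py in (0, 1):
        for px in (0, 1):
            p1 = _pool_phase(f1, py, px)
            g = _run_conv_block(block2, p1)
            for qy in (0, 1):
                for qx in (0, 1):
                    maps[(py, px, qy, qx)] = _pool_phase(g, qy, qx)

    ny = (th - window) // stride + 1
    nx = (tw - window) // stride + 1
    probs = np.empty((ny, nx))
    fy = window // 4          # feature window side after two poolings (5)

    # group lattice windows by pooling phase so each group reads one map
    ys = np.arange(ny) * stride
    xs = np.arange(nx) * stride
    py_all, s1y = ys % 2, ys // 2
    qy_all, ty = s1y % 2, s1y // 2
    px_all, s1x = xs % 2, xs // 2
    qx_all, tx = s1x % 2, s1x // 2

    for py in (0, 1):
        for qy in (0, 1):
            sel_y = np.flatnonzero((py_all == py) & (qy_all == qy))
            if sel_y.size == 0:
                continue
            for px in (0, 1):
                for qx in (0, 1):
                    sel_x = np.flatnonzero((px_all == px) & (qx_all == qx))
                    if sel_x.size == 0:
                        continue
                    m = maps[(py, px, qy, qx)]
                    wins = sliding_window_view(m, (fy, fy), axis=(0, 1))
                    gy, gx = np.meshgrid(ty[sel_y], tx[sel_x], indexing="ij")
                    feat = wins[gy.ravel(), gx.ravel()]       # (n, C, 5, 5)
                    feat = feat.transpose(0, 2, 3, 1).reshape(len(feat), -1)
                    out = np.empty(len(feat))
                    for s in range(0, len(feat), _HEAD_CHUNK):
                        f = feat[s:s + _HEAD_CHUNK]
                        h1 = np.maximum(f @ dense1.W + dense1.b, 0)
                        out[s:s + _HEAD_CHUNK] = (h1 @ dense2.W + dense2.b).ravel()
                    probs[np.ix_(sel_y, sel_x)] = _nn.sigmoid(out).reshape(
                        len(sel_y), len(sel_x))
    return probs
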