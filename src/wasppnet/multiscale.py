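"""Multi-scale feature modules: SPP, ASPP, direct and waterfall flows.

Two families of parallel branches extract context at several scales from
one feature map:

* an **SPP branch** is conv(3x3, same) -> average pool (kernel = stride =
  pool side) -> batch norm -> ReLU; larger pool sides summarize coarser
  regions;
* an **ASPP branch** is a 3x3 atrous (dilated) convolution at rate ``r``
  (same padding) -> batch norm -> ReLU; the kernel taps are spaced ``r``
  pixels apart (gap ``r - 1``), enlarging the field of view without
  adding parameters or losing resolution.

Branch outputs are bilinearly resized back to the module input size and
concatenated along channels together with a skip copy of the input.  In
the **direct** flow every branch reads the module input; in the
**waterfall** flow branch ``i`` reads branch ``i-1``'s (un-resized)
post-activation output, cascading fields of view.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import (AvgPool2d, BatchNorm2d, BilinearResize, Conv2d,
                 GeometryError, Layer, ReLU, Sequential)

__all__ = [
    "atrous_conv1d", "atrous_conv2d", "effective_span",
    "SPPBranch", "ASPPBranch", "MultiScaleBlock",
    "aggregate_direct", "aggregate_waterfall",
]


# ---------------------------------------------------------------------------
# Atrous convolution primitives
# ---------------------------------------------------------------------------

def effective_span(k_taps: int, rate: int) -> int:
    """Input extent one output value sees: ``(k_taps - 1) * rate + 1``."""
    return (k_taps - 1) * rate + 1


def _same_pad(k_taps: int, rate: int) -> tuple[int, int]:
    total = effective_span(k_taps, rate) - 1
    return total // 2, total - total // 2


def atrous_conv1d(x: np.ndarray, f: np.ndarray, r: int,
                  padding_mode: str = "valid") -> np.ndarray:
    """1-D atrous convolution: ``W[n] = sum_k x[n + r*k] * f[k]``."""
    x = np.asarray(x, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if r < 1:
        raise ValueError("dilation rate must be >= 1")
    k = f.shape[0]
    if padding_mode == "same":
        lo, hi = _same_pad(k, r)
        x = np.pad(x, (lo, hi))
    span = effective_span(k, r)
    n_out = x.shape[0] - span + 1
    if n_out < 1:
        raise GeometryError(
            f"effective span {span} exceeds input length {x.shape[0]}")
    out = np.zeros(n_out)
    for i in range(k):
        out += f[i] * x[i * r:i * r + n_out]
    return out


def atrous_conv2d(x: np.ndarray, f: np.ndarray, r: int,
                  padding_mode: str = "valid") -> np.ndarray:
    """2-D atrous convolution of a single-channel map.

    Applies the 1-D tap rule in both spatial dimensions:
    ``out[m, n] = sum_{i,j} x[m + r*i, n + r*j] * f[i, j]``.  With
    ``padding_mode='same'`` zero padding preserves the spatial size.
    """
    x = np.asarray(x, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if r < 1:
        raise ValueError("dilation rate must be >= 1")
    kh, kw = f.shape
    if padding_mode == "same":
        plo_h, phi_h = _same_pad(kh, r)
        plo_w, phi_w = _same_pad(kw, r)
        x = np.pad(x, ((plo_h, phi_h), (plo_w, phi_w)))
    sh, sw = effective_span(kh, r), effective_span(kw, r)
    oh, ow = x.shape[0] - sh + 1, x.shape[1] - sw + 1
    if oh < 1 or ow < 1:
        raise GeometryError(
            f"effective span {sh}x{sw} exceeds input {x.shape}")
    out = np.zeros((oh, ow))
    for i in range(kh):
        for j in range(kw):
            out += f[i, j] * x[i * r:i * r + oh, j * r:j * r + ow]
    return out


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------

BRANCH_KERNEL = 3  # 3x3 branch convs for both SPP and ASPP


class _Branch(Sequential):
    """One parallel branch; subclasses set the op chain."""

    def __init__(self, layers, out_channels: int) -> None:
        super().__init__(layers)
        self.out_channels = out_channels


class SPPBranch(_Branch):
    """conv(3x3, same) -> avg pool(pool_side) -> BN -> ReLU."""

    def __init__(self, in_channels: int, pool_side: int, out_channels: int,
                 rng: np.random.Generator | None = None) -> None:
        if pool_side < 2:
            raise ValueError("pool_side must be >= 2")
        self.pool_side = pool_side
        super().__init__([
            ("conv", Conv2d(in_channels, out_channels, BRANCH_KERNEL,
                            padding=BRANCH_KERNEL // 2, rng=rng)),
            ("pool", AvgPool2d(pool_side)),
            ("bn", BatchNorm2d(out_channels)),
            ("relu", ReLU()),
        ], out_channels)

    def output_side(self, side: int) -> int:
        out = side // self.pool_side
        if out < 1:
            raise GeometryError(
                f"pool side {self.pool_side} exceeds spatial size {side}")
        return out


class ASPPBranch(_Branch):
    """3x3 atrous conv (same padding, dilation = rate) -> BN -> ReLU."""

    def __init__(self, in_channels: int, rate: int, out_channels: int,
                 rng: np.random.Generator | None = None) -> None:
        if rate < 1:
            raise ValueError("dilation rate must be >= 1")
        self.rate = rate
        super().__init__([
            ("conv", Conv2d(in_channels, out_channels, BRANCH_KERNEL,
                            padding=(BRANCH_KERNEL // 2) * rate,
                            dilation=rate, rng=rng)),
            ("bn", BatchNorm2d(out_channels)),
            ("relu", ReLU()),
        ], out_channels)

    def output_side(self, side: int) -> int:
        return side  # same padding preserves spatial size


# ---------------------------------------------------------------------------
# Aggregation block
# ---------------------------------------------------------------------------

class MultiScaleBlock(Layer):
    """Parallel multi-scale branches with skip connection and
    resize-concatenate fusion.

    Parameters
    ----------
    kind : {'spp', 'aspp'}
    flow : {'direct', 'waterfall'}
    branch_params : pool side lengths (spp) or dilation rates (aspp),
        strictly increasing.
    in_channels, input_side : shape of the feature map the block receives;
        the spatial side is needed up front to validate waterfall-SPP
        geometry (cumulative pooling can exhaust the map) and is checked
        again at run time.
    branch_channels : conv filters per branch.
    chain_resized : for the waterfall flow only, chain each branch from
        the previous branch's *resized* output instead of its raw pooled
        output.  Required for waterfall SPP with large pool sets, whose
        raw chaining would shrink the map below one pixel; such configs
        are otherwise rejected at construction.

    Output channels = ``in_channels + n_branches * branch_channels``.
    """

    def __init__(self, kind: str, flow: str, branch_params: list[int],
                 in_channels: int, input_side: int,
                 branch_channels: int = 64, chain_resized: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kind not in ("spp", "aspp"):
            raise ValueError(f"unknown module kind {kind!r}")
        if flow not in ("direct", "waterfall"):
            raise ValueError(f"unknown flow {flow!r}")
        if len(branch_params) == 0:
            raise ValueError("at least one branch required")
        if list(branch_params) != sorted(set(branch_params)):
            raise ValueError("branch_params must be strictly increasing")
        self.kind = kind
        self.flow = flow
        self.branch_params = list(branch_params)
        self.in_channels = in_channels
        self.input_side = input_side
        self.branch_channels = branch_channels
        self.chain_resized = chain_resized
        rng = rng or np.random.default_rng()

        branch_cls = SPPBranch if kind == "spp" else ASPPBranch
        self.branches: list[_Branch] = []
        side = input_side
        for i, p in enumerate(self.branch_params):
            if flow == "waterfall" and i > 0:
                b_in = branch_channels
                b_side = input_side if chain_resized else side
            else:
                b_in = in_channels
                b_side = input_side
            branch = branch_cls(b_in, p, branch_channels, rng=rng)
            try:
                side = branch.output_side(b_side)
            except GeometryError as err:
                raise GeometryError(
                    f"{kind} waterfall stage {i + 1} "
                    f"(param {p}): {err}") from err
            self.branches.append(branch)
        self.resizes = [BilinearResize(input_side, input_side)
                        for _ in self.branches]

    @property
    def out_channels(self) -> int:
        return self.in_channels + len(self.branches) * self.branch_channels

    def forward(self, x, train=False):
        if x.shape[1] != self.in_channels or x.shape[2] != self.input_side:
            raise GeometryError(
                f"multi-scale block built for {self.in_channels}x"
                f"{self.input_side}x{self.input_side}, got {x.shape[1:]}")
        outs = [x]
        inp = x
        for branch, resize in zip(self.branches, self.resizes):
            raw = branch.forward(inp, train=train)
            resized = resize.forward(raw, train=train)
            outs.append(resized)
            if self.flow == "waterfall":
                inp = resized if self.chain_resized else raw
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        c_in, c_b = self.in_channels, self.branch_channels
        g = [grad[:, c_in + i * c_b: c_in + (i + 1) * c_b]
             for i in range(len(self.branches))]
        dx = grad[:, :c_in].copy()
        waterfall = self.flow == "waterfall"
        carry = None  # grad w.r.t. the chained output of the earlier branch
        for i in reversed(range(len(self.branches))):
            g_out = g[i]
            if waterfall and self.chain_resized and carry is not None:
                g_out = g_out + carry          # carry targets resized output
            d_raw = self.resizes[i].backward(g_out)
            if waterfall and not self.chain_resized and carry is not None:
                d_raw = d_raw + carry          # carry targets raw output
            d_in = self.branches[i].backward(d_raw)
            if not waterfall or i == 0:
                dx += d_in
                carry = None
            else:
                carry = d_in
        return dx

    # -- parameter traversal hooks used by Sequential -----------------------

    def parameters_nested(self, prefix: str):
        for i, branch in enumerate(self.branches):
            for sub, layer, key in branch.parameters():
                yield f"{prefix}/branch{i + 1}/{sub}", layer, key

    def all_layers_nested(self, prefix: str):
        for i, branch in enumerate(self.branches):
            yield from branch._all_layers(f"{prefix}branch{i + 1}/")

    def n_params(self) -> int:
        return int(sum(b.n_params() for b in self.branches))


# ---------------------------------------------------------------------------
# Functional aggregation (builds a block, runs one eval-mode pass)
# ---------------------------------------------------------------------------

def _aggregate(x: np.ndarray, kind: str, branch_params, flow: str,
               branch_channels: int, seed: int,
               chain_resized: bool = False) -> np.ndarray:
    x = np.asarray(x, dtype=nn.DTYPE)
    if x.ndim == 3:
        x = x[None]
    if len(branch_params) == 0:
        return x  # empty aggregation is the identity
    block = MultiScaleBlock(kind, flow, list(branch_params), x.shape[1],
                            x.shape[2], branch_channels=branch_channels,
                            chain_resized=chain_resized,
                            rng=np.random.default_rng(seed))
    return block.forward(x, train=False)


def aggregate_direct(x, kind: str, branch_params, branch_channels: int = 64,
                     seed: int = 0):
    """Run a direct-flow multi-scale block over ``x`` (fresh seeded
    weights); returns the concatenated feature map."""
    return _aggregate(x, kind, branch_params, "direct", branch_channels, seed)


def aggregate_waterfall(x, kind: str, branch_params,
                        branch_channels: int = 64, seed: int = 0,
                        chain_resized: bool = False):
    """Run a waterfall-flow multi-scale block over ``x``; see
    :class:`MultiScaleBlock` for the chaining rule."""
    return _aggregate(x, kind, branch_params, "waterfall", branch_channels,
                      seed, chain_resized=chain_resized)
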