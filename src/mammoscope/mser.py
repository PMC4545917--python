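"""Maximally stable extremal regions (MSER) for bright nuclei.

The detector operates on upper level sets of an 8-bit image: for every
threshold t in 0..255 the connected components of ``{pixels >= t}`` are
tracked, together with their areas, in a component tree (max-tree).  The
stability of a component C at threshold t is the relative area variation

    q(t) = (area(t - delta/2) - area(t + delta/2)) / area(t)

where the area function is continued through the nesting chain: toward
lower thresholds through the enclosing components, toward higher thresholds
through the iteratively largest nested component.  Thresholds at which q is
a local minimum along the chain are selected (ties keep the lowest
threshold of a tied run); selections are filtered by area bounds and a
maximum variation, and nested near-duplicates are removed when their
relative area difference (diversity) is below a minimum.  The full-image
component is never reported.

A brute-force oracle (:func:`mser_brute_force_oracle`) recomputes the same
contract by explicit labeling of all 256 level sets; the fast max-tree path
must agree with it pixel-for-pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import ndimage

from .calibration import CalibratedImage

__all__ = [
    "MSERParams",
    "ExtremalRegion",
    "ComponentTree",
    "build_component_tree",
    "stability",
    "detect_mser",
    "mser_brute_force_oracle",
    "regions_to_label_mask",
]

#: 8-connectivity structuring element shared by all labeling steps
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MSERParams:
    """Tuning parameters of the detector.

    Defaults are the operating point used for proflavine-stained nuclei:
    area gates of 35-500 px (5-19 um equivalent diameter at 0.75 um/px),
    ``max_variation`` 2.5, ``min_diversity`` 0.5 and ``delta`` 6, all on the
    0-255 relative-intensity scale.
    """

    min_area: int = 35
    max_area: int = 500
    max_variation: float = 2.5
    min_diversity: float = 0.5
    delta: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("require 0 < min_area < max_area")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if not 0.0 <= self.min_diversity <= 1.0:
            raise ValueError("min_diversity must lie in [0, 1]")
        if not self.max_variation > 0:
            raise ValueError("max_variation must be positive")


@dataclass
class ExtremalRegion:
    """One selected maximally stable region."""

    pixels: np.ndarray          # (N, 2) array of (row, col) coordinates
    level: int                  # threshold at which the region was selected
    area: int
    stability: float            # q at the selection threshold
    area_record: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)

    def pixel_set(self, width: int) -> frozenset[int]:
        """Flat pixel indices, for order-free comparisons."""
        return frozenset((self.pixels[:, 0] * width + self.pixels[:, 1]).tolist())


# ---------------------------------------------------------------------------
# component tree (max-tree)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _union_find_parents(vals, order, H, W):
    """Union-find max-tree build: pixels processed from bright to dark,
    then parent pointers canonicalized in reverse (dark-to-bright) order."""
    n = H * W
    parent = np.full(n, -1, np.int64)
    zpar = np.full(n, -1, np.int64)
    for k in range(n):
        p = order[k]
        parent[p] = p
        zpar[p] = p
        r0 = p // W
        c0 = p % W
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                r = r0 + dr
                c = c0 + dc
                if 0 <= r < H and 0 <= c < W:
                    q = r * W + c
                    if zpar[q] != -1:
                        root = q
                        while zpar[root] != root:
                            root = zpar[root]
                        cur = q
                        while zpar[cur] != root:
                            nxt = zpar[cur]
                            zpar[cur] = root
                            cur = nxt
                        if root != p:
                            parent[root] = p
                            zpar[root] = p
    for k in range(n - 1, -1, -1):
        p = order[k]
        q = parent[p]
        if vals[parent[q]] == vals[q]:
            parent[p] = parent[q]
    return parent


@njit(cache=True)
def _accumulate_nodes(node_parent, node_order_desc, area, min_pix):
    """Propagate subtree areas / min pixel ids leaves-to-root and pick each
    node's largest child (ties -> smallest subtree pixel id)."""
    M = node_parent.size
    child_best = np.full(M, -1, np.int64)
    for k in range(M):
        i = node_order_desc[k]
        p = node_parent[i]
        if p != -1:
            area[p] += area[i]
            if min_pix[i] < min_pix[p]:
                min_pix[p] = min_pix[i]
    for i in range(M):
        p = node_parent[i]
        if p != -1:
            b = child_best[p]
            if (
                b == -1
                or area[i] > area[b]
                or (area[i] == area[b] and min_pix[i] < min_pix[b])
            ):
                child_best[p] = i
    return child_best


@njit(cache=True)
def _chain_q(level, parent, area, largest_child, i, t, h):
    """q of node i's component evaluated at threshold t in its interval."""
    tlo = int(math.ceil(t - h))
    if tlo < 0:
        tlo = 0
    thi = int(math.ceil(t + h))
    if thi > 255:
        thi = 255
    a = i
    while parent[a] != -1 and level[parent[a]] >= tlo:
        a = parent[a]
    a_lo = area[a]
    m = i
    a_hi = 0
    while True:
        if level[m] >= thi:
            a_hi = area[m]
            break
        c = largest_child[m]
        if c == -1:
            break
        m = c
    return (a_lo - a_hi) / area[i]


@njit(cache=True)
def _select_maxtree(
    level, parent, area, largest_child, delta, min_area, max_area, max_variation
):
    """Scan q(t) along every nesting chain; return (node, t, q) selections.

    A threshold t in node i's interval is selected when q(t) is strictly
    below the previous chain value and not above the next one (so a tied
    run keeps only its lowest threshold); the root node is skipped.
    """
    M = level.size
    h = delta / 2.0
    qfirst = np.empty(M, np.float64)
    qlast = np.empty(M, np.float64)
    for i in range(M):
        lo = level[parent[i]] if parent[i] != -1 else np.int64(-1)
        qfirst[i] = _chain_q(level, parent, area, largest_child, i, lo + 1, h)
        qlast[i] = _chain_q(level, parent, area, largest_child, i, level[i], h)

    sel_node = []
    sel_t = []
    sel_q = []
    for i in range(M):
        if parent[i] == -1:
            continue
        if area[i] < min_area or area[i] > max_area:
            continue
        lo = level[parent[i]]
        hi = level[i]
        c = largest_child[i]
        q_prev = qlast[parent[i]]
        q_t = qfirst[i]
        for t in range(lo + 1, hi + 1):
            if t < hi:
                q_next = _chain_q(level, parent, area, largest_child, i, t + 1, h)
            else:
                q_next = qfirst[c] if c != -1 else np.inf
            if q_t < q_prev and q_t <= q_next and q_t <= max_variation:
                sel_node.append(i)
                sel_t.append(t)
                sel_q.append(q_t)
            q_prev = q_t
            q_t = q_next
    return sel_node, sel_t, sel_q


class ComponentTree:
    """Canonical max-tree of an 8-bit image.

    Each node is a connected component of an upper level set over a
    contiguous threshold interval ``(level[parent], level[node]]``; its
    pixel count over that interval is ``area[node]`` (subtree total).
    """

    def __init__(self, image: CalibratedImage):
        px = image.pixels
        if px.size == 0:
            raise ValueError("cannot build a component tree of an empty image")
        H, W = px.shape
        vals = px.reshape(-1).astype(np.int64)
        # bright-to-dark processing order (stable within equal values)
        order = np.argsort(-vals, kind="stable").astype(np.int64)
        parent_px = _union_find_parents(vals, order, H, W)

        idx = np.arange(vals.size)
        is_canon = (parent_px == idx) | (vals[parent_px] != vals)
        canon_pixels = np.flatnonzero(is_canon)
        M = canon_pixels.size
        node_index = np.full(vals.size, -1, np.int64)
        node_index[canon_pixels] = np.arange(M)

        node_of_pixel = node_index[np.where(is_canon, idx, parent_px)]
        self.node_of_pixel = node_of_pixel
        self.level = vals[canon_pixels]
        par = parent_px[canon_pixels]
        node_parent = node_index[par].copy()
        node_parent[par == canon_pixels] = -1
        self.parent = node_parent

        # direct pixels grouped per node (stable sort: ascending flat index)
        counts = np.bincount(node_of_pixel, minlength=M)
        self._px_sorted = np.argsort(node_of_pixel, kind="stable")
        self._px_start = np.concatenate(([0], np.cumsum(counts)))

        area = counts.astype(np.int64)
        min_pix = self._px_sorted[self._px_start[:-1]].astype(np.int64)
        order_desc = np.argsort(-self.level, kind="stable").astype(np.int64)
        self.largest_child = _accumulate_nodes(node_parent, order_desc, area, min_pix)
        self.area = area
        self.min_pixel = min_pix

        # children grouped per parent node
        ch_counts = np.bincount(node_parent + 1, minlength=M + 1)
        self._ch_sorted = np.argsort(node_parent, kind="stable")
        self._ch_start = np.concatenate(([0], np.cumsum(ch_counts)))

        self.shape = (H, W)

    @property
    def n_nodes(self) -> int:
        return int(self.level.size)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self, node: int) -> np.ndarray:
        lo, hi = self._ch_start[node + 1], self._ch_start[node + 2]
        return self._ch_sorted[lo:hi]

    def components_at(self, t: int) -> list[tuple[int, int]]:
        """Nodes active at threshold ``t`` as (node index, area) pairs."""
        if t < 0 or t > 255:
            return []
        lvl = self.level
        if t <= lvl[self.root]:
            return [(self.root, int(self.area[self.root]))]
        par = self.parent
        par_lvl = np.where(par == -1, np.int64(-1), lvl[np.maximum(par, 0)])
        active = np.flatnonzero((lvl >= t) & (par_lvl < t) & (par != -1))
        return [(int(i), int(self.area[i])) for i in active]

    def node_pixels(self, node: int) -> np.ndarray:
        """(N, 2) row/col coordinates of the node's full component."""
        flats = []
        stack = [int(node)]
        while stack:
            i = stack.pop()
            flats.append(self._px_sorted[self._px_start[i]:self._px_start[i + 1]])
            stack.extend(int(c) for c in self.children(i))
        flat = np.concatenate(flats)
        W = self.shape[1]
        return np.column_stack((flat // W, flat % W))

    def chain_q(self, node: int, t: int, delta: int) -> float:
        """Stability of ``node``'s component at threshold ``t``."""
        lo = self.level[self.parent[node]] if self.parent[node] != -1 else -1
        if not lo < t <= self.level[node]:
            raise ValueError(f"threshold {t} outside node interval ({lo}, {self.level[node]}]")
        return float(
            _chain_q(
                self.level, self.parent, self.area, self.largest_child,
                int(node), int(t), delta / 2.0,
            )
        )

    def chain_area_record(self, node: int) -> dict[int, int]:
        """Area of the nesting chain through ``node``, keyed by threshold."""
        rec = {}
        a = node
        while a != -1:
            rec[int(self.level[a])] = int(self.area[a])
            a = int(self.parent[a])
        m = node
        while self.largest_child[m] != -1:
            m = int(self.largest_child[m])
            rec[int(self.level[m])] = int(self.area[m])
        return dict(sorted(rec.items()))


def build_component_tree(image: CalibratedImage) -> ComponentTree:
    """Build the max-tree of all upper-level-set components of ``image``."""
    return ComponentTree(image)


def stability(area_record: Mapping[int, int], t: int, delta: int) -> float:
    """Relative area variation of a region chain at threshold ``t``.

    ``area_record`` maps thresholds to chain areas; the area function is the
    step continuation taking, at a query threshold, the value recorded at
    the smallest recorded threshold >= the query (zero above the top of the
    chain).  Query thresholds are clamped to [0, 255].
    """
    if not area_record:
        raise ValueError("empty area record")
    keys = sorted(area_record)
    h = delta / 2.0

    def area_at(tau: float) -> int:
        tau = min(max(tau, 0.0), 255.0)
        tq = math.ceil(tau)
        for k in keys:
            if k >= tq:
                return area_record[k]
        return 0

    a_t = area_at(t)
    if a_t == 0:
        raise ValueError(f"area undefined (zero) at threshold {t}")
    return (area_at(t - h) - area_at(t + h)) / a_t


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_mser(
    image: CalibratedImage, params: MSERParams | None = None
) -> list[ExtremalRegion]:
    """Detect bright maximally stable extremal regions via the max-tree."""
    params = params or MSERParams()
    tree = build_component_tree(image)
    nodes, ts, qs = _select_maxtree(
        tree.level,
        tree.parent,
        tree.area,
        tree.largest_child,
        int(params.delta),
        int(params.min_area),
        int(params.max_area),
        float(params.max_variation),
    )
    if len(nodes) == 0:
        return []

    # diversity pruning: deepest selection first, compare with the nearest
    # surviving selected enclosing region (same node at a lower threshold or
    # an ancestor node); discard the nested one when diversity is too small
    sel = sorted(
        range(len(nodes)),
        key=lambda k: (-ts[k], int(tree.min_pixel[nodes[k]]), nodes[k]),
    )
    by_node: dict[int, list[int]] = {}
    for k in range(len(nodes)):
        by_node.setdefault(int(nodes[k]), []).append(k)
    for lst in by_node.values():
        lst.sort(key=lambda k: ts[k])
    surviving = set(range(len(nodes)))

    def nearest_surviving_ancestor(k: int) -> int | None:
        node, t = int(nodes[k]), ts[k]
        j = node
        while j != -1:
            cands = [
                m for m in by_node.get(j, ())
                if m in surviving and (j != node or ts[m] < t)
            ]
            if cands:
                return max(cands, key=lambda m: ts[m])
            j = int(tree.parent[j])
        return None

    for k in sel:
        a = nearest_surviving_ancestor(k)
        if a is None:
            continue
        big = int(tree.area[nodes[a]])
        small = int(tree.area[nodes[k]])
        if (big - small) / big < params.min_diversity:
            surviving.discard(k)

    regions = []
    for k in sorted(
        surviving, key=lambda k: (int(tree.min_pixel[nodes[k]]), ts[k])
    ):
        i = int(nodes[k])
        regions.append(
            ExtremalRegion(
                pixels=tree.node_pixels(i),
                level=int(ts[k]),
                area=int(tree.area[i]),
                stability=float(qs[k]),
                area_record=tree.chain_area_record(i),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def mser_brute_force_oracle(
    image: CalibratedImage, params: MSERParams | None = None
) -> list[ExtremalRegion]:
    """Naive MSER: label all 256 level sets explicitly.

    Implements the identical output contract to :func:`detect_mser` without
    a component tree, for verification on small images.
    """
    params = params or MSERParams()
    px = image.pixels
    n = px.size
    H, W = px.shape
    vmax = int(px.max())
    h = params.delta / 2.0
    T = vmax + 1  # number of occupied threshold levels (0..vmax)

    labs: list[np.ndarray] = []
    areas: list[np.ndarray] = []
    minpix: list[np.ndarray] = []
    for t in range(T):
        lab, nlab = ndimage.label(px >= t, structure=_STRUCT8)
        lab = lab.reshape(-1)
        cnt = np.bincount(lab, minlength=nlab + 1).astype(np.int64)
        cnt[0] = 0  # background is not a component
        mp = np.full(nlab + 1, n, np.int64)
        np.minimum.at(mp, lab, np.arange(n))
        labs.append(lab)
        areas.append(cnt)
        minpix.append(mp)

    # containment maps: cont[t][L] = enclosing label at t-1 (cont[0] = self);
    # down [t][L] = largest nested label at t+1 (0 if none)
    cont: list[np.ndarray] = []
    down: list[np.ndarray] = []
    for t in range(T):
        nlab = areas[t].size - 1
        c = np.zeros(nlab + 1, np.int64)
        if t > 0 and nlab:
            c[1:] = labs[t - 1][minpix[t][1:]]
        cont.append(c)
        d = np.zeros(nlab + 1, np.int64)
        if t + 1 < T:
            up = labs[t][minpix[t + 1][1:]] if areas[t + 1].size > 1 else np.array([], np.int64)
            for L1, Lp in enumerate(up, start=1):
                a1, m1 = areas[t + 1][L1], minpix[t + 1][L1]
                b = d[Lp]
                if b == 0 or a1 > areas[t + 1][b] or (
                    a1 == areas[t + 1][b] and m1 < minpix[t + 1][b]
                ):
                    d[Lp] = L1
        down.append(d)

    def q_of(t: int, L: int) -> float:
        tlo = max(math.ceil(t - h), 0)
        s, cur = t, L
        while s > tlo:
            cur = int(cont[s][cur])
            s -= 1
        a_lo = int(areas[tlo][cur])
        thi = min(math.ceil(t + h), 255)
        s, cur = t, L
        a_hi = int(areas[t][L])
        while s < thi:
            if s + 1 >= T:
                a_hi = 0
                break
            cur = int(down[s][cur])
            if cur == 0:
                a_hi = 0
                break
            s += 1
            a_hi = int(areas[s][cur])
        return (a_lo - a_hi) / int(areas[t][L])

    qv = [
        np.array([np.inf] + [q_of(t, L) for L in range(1, areas[t].size)])
        for t in range(T)
    ]

    selected: list[tuple[int, int]] = []
    for t in range(T):
        for L in range(1, areas[t].size):
            a = int(areas[t][L])
            if a == 0 or a == n:  # root (full image) never reported
                continue
            if not params.min_area <= a <= params.max_area:
                continue
            qi = qv[t][L]
            if qi > params.max_variation:
                continue
            q_prev = qv[t - 1][int(cont[t][L])] if t > 0 else np.inf
            if not qi < q_prev:
                continue
            dn = int(down[t][L]) if t + 1 < T else 0
            q_next = qv[t + 1][dn] if dn else np.inf
            if not qi <= q_next:
                continue
            selected.append((t, L))

    # diversity pruning, deepest selection first
    surviving = set(selected)

    def nearest_surviving_ancestor(t: int, L: int) -> tuple[int, int] | None:
        while t > 0:
            L = int(cont[t][L])
            t -= 1
            if (t, L) in surviving:
                return (t, L)
        return None

    order = sorted(selected, key=lambda nd: (-nd[0], int(minpix[nd[0]][nd[1]])))
    for t, L in order:
        if (t, L) not in surviving:
            continue
        anc = nearest_surviving_ancestor(t, L)
        if anc is None:
            continue
        big = int(areas[anc[0]][anc[1]])
        small = int(areas[t][L])
        if (big - small) / big < params.min_diversity:
            surviving.discard((t, L))

    regions = []
    for t, L in sorted(
        surviving, key=lambda nd: (int(minpix[nd[0]][nd[1]]), nd[0])
    ):
        flat = np.flatnonzero(labs[t] == L)
        # chain area record at thresholds where the chain area changes
        rec: dict[int, int] = {}
        s, cur = t, L
        while True:
            rec[s] = int(areas[s][cur])
            if s == 0:
                break
            cur = int(cont[s][cur])
            s -= 1
        rec_up = {max(k for k, v2 in rec.items() if v2 == v): v for v in set(rec.values())}
        rec = {}
        s, cur = t, L
        while s + 1 < T:
            nxt = int(down[s][cur])
            if nxt == 0:
                break
            s += 1
            cur = nxt
            rec[s] = int(areas[s][cur])
        rec_dn = {max(k for k, v2 in rec.items() if v2 == v): v for v in set(rec.values())}
        merged: dict[int, int] = {}
        for k, v in {**rec_up, **rec_dn}.items():
            if v not in merged.values() or k > max(kk for kk, vv in merged.items() if vv == v):
                merged = {kk: vv for kk, vv in merged.items() if vv != v}
                merged[k] = v
        record = dict(sorted(merged.items()))
        regions.append(
            ExtremalRegion(
                pixels=np.column_stack((flat // W, flat % W)),
                level=t,
                area=int(areas[t][L]),
                stability=float(qv[t][L]),
                area_record=record,
            )
        )
    return regions


def regions_to_label_mask(
    regions: Sequence[ExtremalRegion], shape: tuple[int, int]
) -> np.ndarray:
    """Union surviving regions and relabel by 8-connectivity (background 0)."""
    fg = np.zeros(shape, dtype=bool)
    for r in regions:
        fg[r.pixels[:, 0], r.pixels[:, 1]] = True
    lab, _ = ndimage.label(fg, structure=_STRUCT8)
    return lab.astype(np.int32)
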