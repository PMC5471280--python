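"""Free-energy landscape assembly and analysis.

Takes the raw per-replica ABF state (bin counts + force sums), pools it
across replicas, integrates the mean-force field into a 2D free-energy
surface ΔG over the sampled bins, and extracts the objects a
conformational-equilibrium argument needs: basins (steepest-descent
catchments of local minima), the minimum free-energy path between two
basins (the path minimizing the *highest* free energy crossed), the
barrier along it, and per-basin escape depths.

Pooling sums counts and force sums, so the pooled mean force is the
sample-count-weighted average of per-replica means — the consistent
estimator for independent runs of one system.  Integration solves the
discrete gradient equations ∂G/∂x = g in least squares over the sampled
mask (unsampled bins are never interpolated); a spanning-tree line
integration is available as a cross-check.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .abf import ABFParams, BinGrid
from .toysystems import AnalyticPotential

__all__ = [
    "FreeEnergyLandscape",
    "Basin",
    "Path",
    "merge_runs",
    "integrate_gradient",
    "find_basins",
    "min_free_energy_path",
    "barrier_height",
    "basin_relative_depth",
    "exact_force_grid",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-neighbor connectivity structure


@dataclass
class FreeEnergyLandscape:
    """Gridded ΔG surface; the global sampled minimum is anchored at 0."""

    axes: list[tuple[float, float, float, int]]  # (min, max, width, n_bins)
    g_values: np.ndarray  # NaN on unsampled bins
    sampled_mask: np.ndarray
    counts: np.ndarray
    n_components: int = 1
    component_labels: np.ndarray | None = None

    def bin_centers(self, axis: int) -> np.ndarray:
        lo, _, w, n = self.axes[axis]
        return lo + w * (np.arange(n) + 0.5)

    def center_of(self, idx: tuple[int, ...]) -> np.ndarray:
        return np.array(
            [lo + w * (i + 0.5) for i, (lo, _, w, _) in zip(idx, self.axes)]
        )

    def global_minimum_bin(self) -> tuple[int, ...]:
        masked = np.where(self.sampled_mask, self.g_values, np.inf)
        return tuple(int(i) for i in np.unravel_index(np.argmin(masked), masked.shape))

    def to_tsv(self, path) -> None:
        """Long-format dump: one row per bin with centers, G, count, mask."""
        nd = len(self.axes)
        with open(path, "w") as fh:
            cols = [f"center{a}" for a in range(nd)] + ["G", "count", "sampled"]
            fh.write("\t".join(cols) + "\n")
            for idx in np.ndindex(*self.g_values.shape):
                c = self.center_of(idx)
                g = self.g_values[idx]
                fh.write(
                    "\t".join(
                        [f"{v:.6g}" for v in c]
                        + [
                            "nan" if np.isnan(g) else f"{g:.6g}",
                            str(int(self.counts[idx])),
                            str(int(self.sampled_mask[idx])),
                        ]
                    )
                    + "\n"
                )

    def to_matrix(self, path) -> None:
        """Contour-ready matrix (rows = axis 0 bins), NaN where unsampled."""
        np.savetxt(path, self.g_values, fmt="%.6g", delimiter="\t")


@dataclass
class Basin:
    """A steepest-descent catchment around one local minimum."""

    minimum_bin: tuple[int, ...]
    member_bins: set
    g_min: float
    label: str

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "minimum_bin": list(self.minimum_bin),
            "g_min": self.g_min,
            "n_bins": len(self.member_bins),
        }


@dataclass
class Path:
    """Ordered 8-connected bin path with arc-length parameterization."""

    bins: list
    arc_length: np.ndarray  # cumulative Å along bin centers
    g_profile: np.ndarray
    rc_normalized: np.ndarray  # generalized reaction coordinate in [0, 1]

    def to_tsv(self, path, axes=None, centers=None) -> None:
        with open(path, "w") as fh:
            fh.write("rc\t" + "\t".join(
                f"x{a}" for a in range(len(self.bins[0]))) + "\tG\n")
            for rc, b, g, c in zip(
                self.rc_normalized, self.bins, self.g_profile,
                centers if centers is not None else [None] * len(self.bins),
            ):
                xy = c if c is not None else b
                fh.write(
                    f"{rc:.6g}\t" + "\t".join(f"{v:.6g}" for v in xy)
                    + f"\t{g:.6g}\n"
                )


def merge_runs(grids: list[BinGrid]) -> BinGrid:
    """Pool replica grids: sum counts and force sums per bin.

    The pooled mean force is then the sample-count-weighted average of
    per-replica mean forces.  All grids must share identical axes.
    """
    if not grids:
        raise ValueError("need at least one grid")
    first = grids[0]
    merged = BinGrid(first.params)
    for g in grids:
        if g.axes != first.axes:
            raise ValueError("cannot merge grids with differing axes")
        merged.counts += g.counts
        merged.force_sums += g.force_sums
    return merged


def _sampled_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    return labels, n


def integrate_gradient(
    grid: BinGrid,
    min_count: int = 1,
    method: str = "lsq",
) -> FreeEnergyLandscape:
    """Integrate bin-mean forces into a free-energy surface.

    The free-energy gradient of a sampled bin is -(mean force).  With
    ``method="lsq"`` (default) the surface solves the discrete gradient
    equations — one equation per axis-adjacent sampled bin pair, with the
    edge gradient taken as the mean of the two bins' gradients — in least
    squares (sparse normal equations).  ``method="line"`` integrates
    along a BFS spanning tree instead, as an independent cross-check;
    it is path-dependent under noise where the least-squares solution
    is not.

    Disconnected sampled regions are integrated independently (each
    anchored to its own minimum); ``n_components > 1`` flags that the
    surface's components share no common reference.
    """
    mask = grid.counts >= max(min_count, 1)
    if not mask.any():
        raise ValueError("no bin reaches min_count; nothing to integrate")
    ndim = grid.params.ndim
    mean_force = np.zeros_like(grid.force_sums)
    mean_force[mask] = grid.force_sums[mask] / grid.counts[mask][..., None]
    gradient = -mean_force  # dG/dξ per bin

    labels, n_comp = _sampled_components(mask)
    g_values = np.full(grid.counts.shape, np.nan)

    bins = [tuple(int(v) for v in b) for b in np.argwhere(mask)]
    index_of = {b: i for i, b in enumerate(bins)}
    widths = grid.params.bin_width

    # Forward difference stencils: axis steps plus (in 2D) both diagonals,
    # so the equation graph is connected exactly where the 8-neighbor
    # sampled mask is.
    if ndim == 1:
        offsets = [(1,)]
    elif ndim == 2:
        offsets = [(1, 0), (0, 1), (1, 1), (1, -1)]
    else:
        offsets = [
            tuple(int(i == a) for i in range(ndim)) for a in range(ndim)
        ]

    if method == "lsq":
        rows, cols, vals, rhs = [], [], [], []
        eq = 0
        for b in bins:
            for off in offsets:
                nb = tuple(bi + oi for bi, oi in zip(b, off))
                if nb in index_of:
                    rows += [eq, eq]
                    cols += [index_of[nb], index_of[b]]
                    vals += [1.0, -1.0]
                    rhs.append(
                        sum(
                            oi * widths[a] * 0.5 * (gradient[b][a] + gradient[nb][a])
                            for a, oi in enumerate(off)
                        )
                    )
                    eq += 1
        # Anchor one bin per component so the system is full rank.
        for comp in range(1, n_comp + 1):
            anchor = next(b for b in bins if labels[b] == comp)
            rows.append(eq)
            cols.append(index_of[anchor])
            vals.append(1.0)
            rhs.append(0.0)
            eq += 1
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(eq, len(bins)))
        b_vec = np.array(rhs)
        sol = spsolve((A.T @ A).tocsc(), A.T @ b_vec)
        for b, i in index_of.items():
            g_values[b] = sol[i]
    elif method == "line":
        # Midpoint-rule accumulation along a BFS spanning tree per component.
        visited = set()
        for comp in range(1, n_comp + 1):
            start = next(b for b in bins if labels[b] == comp)
            g_values[start] = 0.0
            queue = [start]
            visited.add(start)
            while queue:
                b = queue.pop(0)
                for off in offsets:
                    for sign in (1, -1):
                        nb = tuple(bi + sign * oi for bi, oi in zip(b, off))
                        if nb in index_of and nb not in visited:
                            dg = sum(
                                sign * oi * widths[a] * 0.5
                                * (gradient[b][a] + gradient[nb][a])
                                for a, oi in enumerate(off)
                            )
                            g_values[nb] = g_values[b] + dg
                            visited.add(nb)
                            queue.append(nb)
    else:
        raise ValueError(f"unknown integration method {method!r}")

    # Anchor each component's minimum to 0, then the global minimum to 0.
    for comp in range(1, n_comp + 1):
        sel = labels == comp
        g_values[sel] -= np.nanmin(g_values[sel])

    return FreeEnergyLandscape(
        axes=list(grid.axes),
        g_values=g_values,
        sampled_mask=mask,
        counts=grid.counts.copy(),
        n_components=n_comp,
        component_labels=labels,
    )


def _neighbors(idx: tuple[int, ...], shape) -> list[tuple[int, ...]]:
    out = []
    if len(idx) == 2:
        i, j = idx
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                    out.append((ni, nj))
    else:
        (i,) = idx
        for di in (-1, 1):
            ni = i + di
            if 0 <= ni < shape[0]:
                out.append((ni,))
    return out


def find_basins(l: FreeEnergyLandscape, min_depth: float = 0.0) -> list[Basin]:
    """Partition the sampled surface into basins by steepest descent.

    Every sampled bin is assigned to the local minimum reached by always
    stepping to the lowest 8-neighbor.  Basins whose escape barrier
    (lowest saddle to any neighboring basin) is shallower than
    ``min_depth`` relative to their own minimum are merged into the
    neighbor across that saddle — this removes noise-scale corrugation.
    Output is sorted by basin minimum, labelled "B0", "B1", ...
    """
    shape = l.g_values.shape
    bins = [tuple(int(v) for v in b) for b in np.argwhere(l.sampled_mask)]
    order = sorted(bins, key=lambda b: (l.g_values[b],) + b)
    assign: dict[tuple[int, ...], int] = {}
    minima: list[tuple[int, ...]] = []
    for b in order:
        lower = [
            nb for nb in _neighbors(b, shape)
            if l.sampled_mask[nb] and (l.g_values[nb],) + nb < (l.g_values[b],) + b
        ]
        if not lower:
            assign[b] = len(minima)
            minima.append(b)
        else:
            steepest = min(lower, key=lambda nb: (l.g_values[nb],) + nb)
            assign[b] = assign[steepest]

    n = len(minima)
    members: list[set] = [set() for _ in range(n)]
    for b, k in assign.items():
        members[k].add(b)

    def saddles() -> dict[tuple[int, int], float]:
        out: dict[tuple[int, int], float] = {}
        for b, k in assign.items():
            for nb in _neighbors(b, shape):
                if l.sampled_mask[nb]:
                    k2 = assign[nb]
                    if k2 != k:
                        key = (min(k, k2), max(k, k2))
                        h = max(l.g_values[b], l.g_values[nb])
                        if key not in out or h < out[key]:
                            out[key] = h
        return out

    # Merge shallow basins into the neighbor across their lowest saddle.
    alive = set(range(n))
    while len(alive) > 1 and min_depth > 0:
        sad = saddles()
        best = None
        for k in alive:
            esc = [
                (h, key) for key, h in sad.items() if k in key
            ]
            if not esc:
                continue
            h, key = min(esc)
            depth = h - l.g_values[minima[k]]
            if depth < min_depth:
                other = key[0] if key[1] == k else key[1]
                # Prefer merging the shallowest offender first.
                if best is None or depth < best[0]:
                    best = (depth, k, other)
        if best is None:
            break
        _, k, other = best
        # Keep the deeper minimum's identity.
        if l.g_values[minima[other]] > l.g_values[minima[k]]:
            k, other = other, k
        for b in members[k]:
            assign[b] = other
        members[other] |= members[k]
        members[k] = set()
        alive.discard(k)

    out = []
    for k in sorted(alive, key=lambda k: (l.g_values[minima[k]],) + minima[k]):
        mb = min(members[k], key=lambda b: (l.g_values[b],) + b)
        out.append(
            Basin(
                minimum_bin=mb,
                member_bins=members[k],
                g_min=float(l.g_values[mb]),
                label="",
            )
        )
    for i, basin in enumerate(out):
        basin.label = f"B{i}"
    return out


def min_free_energy_path(
    l: FreeEnergyLandscape, start: Basin, end: Basin
) -> Path:
    """Minimum free-energy path between two basin minima.

    Minimax (widest-path) criterion over 8-connected sampled bins: among
    all paths the one minimizing the *maximum* G crossed — the quantity
    whose peak is the barrier — with ties broken by minimal summed G and
    then lexicographic bin order, making the result deterministic.
    """
    s, e = start.minimum_bin, end.minimum_bin
    if (
        l.component_labels is not None
        and l.component_labels[s] != l.component_labels[e]
    ):
        raise ValueError("basins lie in disconnected sampled components")
    shape = l.g_values.shape
    g = l.g_values
    best: dict[tuple[int, ...], tuple[float, float]] = {}
    prev: dict[tuple[int, ...], tuple[int, ...] | None] = {}
    start_key = (float(g[s]), float(g[s]))
    heap = [(start_key[0], start_key[1], s, None)]
    while heap:
        maxg, sumg, b, pb = heapq.heappop(heap)
        if b in best and (maxg, sumg) >= best[b]:
            continue
        best[b] = (maxg, sumg)
        prev[b] = pb
        if b == e:
            break
        for nb in _neighbors(b, shape):
            if not l.sampled_mask[nb]:
                continue
            nmax = max(maxg, float(g[nb]))
            nsum = sumg + float(g[nb])
            if nb not in best or (nmax, nsum) < best[nb]:
                heapq.heappush(heap, (nmax, nsum, nb, b))
    if e not in best:
        raise ValueError("no sampled path connects the two basins")
    bins = []
    b = e
    while b is not None:
        bins.append(b)
        b = prev[b]
    bins.reverse()
    centers = [l.center_of(b) for b in bins]
    seg = [0.0] + [
        float(np.linalg.norm(c2 - c1)) for c1, c2 in zip(centers, centers[1:])
    ]
    arc = np.cumsum(seg)
    total = arc[-1] if arc[-1] > 0 else 1.0
    return Path(
        bins=bins,
        arc_length=arc,
        g_profile=np.array([float(g[b]) for b in bins]),
        rc_normalized=arc / total,
    )


def barrier_height(p: Path) -> float:
    """Highest free energy along the path relative to its starting point."""
    return float(np.max(p.g_profile) - p.g_profile[0])


def basin_relative_depth(l: FreeEnergyLandscape, b: Basin, p: Path) -> float:
    """Escape barrier of basin ``b`` along path ``p``: the highest G the
    path crosses minus the basin's minimum."""
    if p.bins[0] != b.minimum_bin and p.bins[-1] != b.minimum_bin:
        raise ValueError("path is not incident to the given basin")
    return float(np.max(p.g_profile) - b.g_min)


def basins_to_json(basins: list[Basin], path=None) -> str:
    payload = json.dumps([b.to_dict() for b in basins], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload + "\n")
    return payload


def exact_force_grid(
    potential: AnalyticPotential,
    ap: ABFParams,
    count: int = 1,
) -> BinGrid:
    """BinGrid holding the *exact* systematic force -∇U at each bin center.

    The noise-free analogue of a converged ABF run; used to validate the
    integrator against the analytic surface."""
    grid = BinGrid(ap)
    centers = [grid.bin_centers(a) for a in range(ap.ndim)]
    for idx in np.ndindex(*grid.n_bins):
        x = np.array([centers[a][i] for a, i in enumerate(idx)])
        grid.counts[idx] = count
        grid.force_sums[idx] = -potential.gradient(x) * count
    return grid
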