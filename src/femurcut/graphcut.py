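"""Phase 3 — seeded binary segmentation by min-cut/max-flow.

The segmentation minimizes a Boykov–Jolly-style energy over binary
labelings A of the boneness map:

    E(A) = sum_p R(p)  +  lambda * sum_{(p,q) in N, p fg, q bg} B(p,q)

The per-voxel term R encodes the operator seeds (Eqs. below use the label
costs as terminal-link capacities): a foreground seed has (R_f, R_b) =
(lambda, 0), a background seed (1, lambda), an unlabelled voxel (0, 1) — a
mild background prior.  The boundary term is asymmetric,

    B(p, q) = exp(-lambda (BJE(p) - BJE(q))^2 / (2 sigma^2))   if BJE(p) > BJE(q)
            = lambda                                            otherwise

so cutting "downhill" across a sharp bright-to-dark transition (cortical
shell -> joint space or soft tissue) is nearly free, while separating
similar or ascending neighbours costs lambda (times the energy weight).
Defaults sigma = 0.25 and lambda = 100.

Two ambiguities of the original formulation are kept behind explicit
dialect flags, with defaults following it literally: whether lambda
multiplies the exponent of B (``lambda_in_exponent``) and whether it also
multiplies the boundary sum of E (``lambda_in_energy``); and whether
R_f/R_b are read as terminal capacities (default; seeds act as near-hard
constraints) or as literal label costs (``regional_as_capacity=False``).

The minimization is exact: the energy is submodular under this
construction, and a minimum s-t cut of the corresponding flow network is a
global optimum.  Two backends are used — NetworkX (float capacities, small
graphs) and ``scipy.sparse.csgraph.maximum_flow`` (integer capacities with
adaptive fixed-point scaling, large grids); the backend choice affects at
most round-off-level tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .volume import BinaryMask, ImageVolume, SeedVolume

__all__ = [
    "GraphCutParams",
    "TermMaps",
    "boundary_term",
    "regional_terms",
    "build_terms",
    "energy",
    "mincut_segment",
]

_CONNECTIVITY_OFFSETS = {
    6: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    18: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
    26: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
         (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)],
}


@dataclass
class GraphCutParams:
    """Graph-cut parameters and dialect flags.

    sigma:
        Noise scale of the boundary term (boneness units).  Too large and
        every pair looks similar, making cuts uniformly expensive.
    lam:
        Weighting factor between regional and boundary terms; also the
        seed terminal capacity, so seeds are near-hard constraints.
    connectivity:
        Neighbourhood system, 6 / 18 / 26.
    """

    sigma: float = 0.25
    lam: float = 100.0
    connectivity: int = 6
    lambda_in_exponent: bool = True
    lambda_in_energy: bool = True
    regional_as_capacity: bool = True
    keep_largest_component: bool = True
    solver: str = "auto"  # "auto" | "networkx" | "scipy"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")
        if self.connectivity not in _CONNECTIVITY_OFFSETS:
            raise ValueError(
                f"connectivity must be 6, 18 or 26, got {self.connectivity}"
            )
        if self.solver not in ("auto", "networkx", "scipy"):
            raise ValueError(f"unknown solver {self.solver!r}")

    @property
    def boundary_weight(self) -> float:
        """Multiplier of the boundary sum in the energy."""
        return self.lam if self.lambda_in_energy else 1.0


@dataclass
class TermMaps:
    """Materialized per-voxel term halves (and the boneness used for B)."""

    r_f: np.ndarray
    r_b: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    bje: np.ndarray | None = None

    def label_costs(self, params: GraphCutParams) -> tuple[np.ndarray, np.ndarray]:
        """(cost of labelling foreground, cost of labelling background).

        Under the capacity reading, labelling a voxel foreground cuts its
        background-terminal link and pays r_b, and vice versa; the literal
        cost reading pays r_f for foreground directly.
        """
        if params.regional_as_capacity:
            return self.r_b, self.r_f
        return self.r_f, self.r_b


def boundary_term(bje_p, bje_q, params: GraphCutParams):
    """Directed boundary penalty B(p, q); scalar or elementwise on arrays.

    Exponential branch when BJE(p) > BJE(q) (descending), lambda otherwise.
    """
    p = np.asarray(bje_p, dtype=np.float64)
    q = np.asarray(bje_q, dtype=np.float64)
    diff2 = (p - q) ** 2 / (2.0 * params.sigma ** 2)
    if params.lambda_in_exponent:
        diff2 = params.lam * diff2
    out = np.where(p > q, np.exp(-diff2), params.lam)
    if out.ndim == 0:
        return float(out)
    return out


def regional_terms(seeds: SeedVolume, params: GraphCutParams) -> TermMaps:
    """Per-voxel term halves from the seed labels.

    foreground seed -> (R_f, R_b) = (lambda, 0); background seed -> (1,
    lambda); unlabelled -> (0, 1).
    """
    fg = seeds.foreground
    bg = seeds.background
    r_f = np.zeros(seeds.shape, dtype=np.float64)
    r_b = np.ones(seeds.shape, dtype=np.float64)
    r_f[fg] = params.lam
    r_b[fg] = 0.0
    r_f[bg] = 1.0
    r_b[bg] = params.lam
    return TermMaps(r_f=r_f, r_b=r_b, spacing=seeds.spacing, origin=seeds.origin)


def build_terms(boneness: ImageVolume, seeds: SeedVolume,
                params: GraphCutParams) -> TermMaps:
    """Regional terms plus the boneness map needed for boundary capacities."""
    boneness.require_same_grid(seeds, "seed image")
    terms = regional_terms(seeds, params)
    terms.bje = np.asarray(boneness.data, dtype=np.float64)
    return terms


def _directed_pairs(shape, offset):
    """Index grids (p, q) for all in-bounds neighbour pairs q = p + offset."""
    sl_p, sl_q = [], []
    for d in offset:
        if d == 0:
            sl_p.append(slice(None))
            sl_q.append(slice(None))
        elif d > 0:
            sl_p.append(slice(None, -d))
            sl_q.append(slice(d, None))
        else:
            sl_p.append(slice(-d, None))
            sl_q.append(slice(None, d))
    return tuple(sl_p), tuple(sl_q)


def energy(labeling: BinaryMask, terms: TermMaps,
           params: GraphCutParams) -> float:
    """Evaluate the segmentation energy E(A) of a binary labeling.

    Regional part: each foreground voxel pays its foreground-label cost,
    each background voxel its background-label cost.  Boundary part: the
    weighted sum of B(p, q) over directed neighbour pairs with p foreground
    and q background.
    """
    if terms.bje is None:
        raise ValueError("TermMaps has no boneness map; use build_terms()")
    lab = labeling.data
    if lab.shape != terms.r_f.shape:
        raise ValueError("labeling grid disagrees with term maps")
    c_fg, c_bg = terms.label_costs(params)
    e = float(c_fg[lab].sum() + c_bg[~lab].sum())
    w = params.boundary_weight
    bje = terms.bje
    for off in _CONNECTIVITY_OFFSETS[params.connectivity]:
        for o in (off, tuple(-d for d in off)):
            sp, sq = _directed_pairs(lab.shape, o)
            cut = lab[sp] & ~lab[sq]
            if cut.any():
                b = boundary_term(bje[sp][cut], bje[sq][cut], params)
                e += w * float(np.sum(b))
    return e


def _solve_networkx(n, src_cap, snk_cap, eu, ev, ecap):
    import networkx as nx

    G = nx.DiGraph()
    S, T = n, n + 1
    G.add_nodes_from(range(n + 2))
    G.add_weighted_edges_from(
        ((S, i, c) for i, c in enumerate(src_cap) if c > 0), weight="capacity")
    G.add_weighted_edges_from(
        ((i, T, c) for i, c in enumerate(snk_cap) if c > 0), weight="capacity")
    G.add_weighted_edges_from(
        ((int(u), int(v), float(c)) for u, v, c in zip(eu, ev, ecap) if c > 0),
        weight="capacity")
    _, (s_side, _) = nx.minimum_cut(G, S, T)
    fg = np.zeros(n, dtype=bool)
    members = np.fromiter((i for i in s_side if i < n), dtype=np.int64)
    fg[members] = True
    return fg


def _solve_scipy(n, src_cap, snk_cap, eu, ev, ecap):
    S, T = n, n + 1
    all_caps = np.concatenate([src_cap, snk_cap, ecap])
    max_cap = all_caps.max() if all_caps.size else 0.0
    if max_cap <= 0:
        return np.zeros(n, dtype=bool)
    # Fixed-point scale: capacities and per-node incident sums must stay
    # within int32 for scipy's solver, as must the total flow.
    cap_limit = (2 ** 31 - 1) / 32.0
    flow_bound = min(src_cap.sum(), snk_cap.sum()) + 1.0
    scale = min(cap_limit / max_cap, (2 ** 31 - 1) / flow_bound)
    rows = np.concatenate([
        np.full(n, S), np.arange(n),          # source links + reverse
        np.arange(n), np.full(n, T),          # sink links + reverse
        eu, ev,
    ])
    cols = np.concatenate([
        np.arange(n), np.full(n, S),
        np.full(n, T), np.arange(n),
        ev, eu,
    ])
    caps = np.concatenate([
        np.floor(src_cap * scale + 0.5), np.zeros(n),
        np.floor(snk_cap * scale + 0.5), np.zeros(n),
        np.floor(ecap * scale + 0.5), np.zeros(len(ecap)),
    ]).astype(np.int32)
    g = coo_matrix((caps, (rows, cols)), shape=(n + 2, n + 2)).tocsr()
    result = maximum_flow(g, S, T)
    residual = g - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    order, _ = breadth_first_order(residual, S, directed=True,
                                   return_predecessors=True)
    fg = np.zeros(n, dtype=bool)
    fg[order[order < n]] = True
    return fg


def mincut_segment(boneness: ImageVolume, seeds: SeedVolume,
                   roi: BinaryMask | None = None,
                   params: GraphCutParams | None = None) -> BinaryMask:
    """Globally minimize the segmentation energy; return the foreground mask.

    Voxels outside ``roi`` are forced background and excluded from the
    graph; faces crossing the ROI boundary carry no penalty, so the
    minimized energy is that of the ROI subgraph.  With the default
    lambda, seeded voxels behave as near-hard constraints.  Cleanup
    (largest 6-connected component) is applied last when
    ``keep_largest_component`` is set.
    """
    if params is None:
        params = GraphCutParams()
    boneness.require_same_grid(seeds, "seed image")
    bje = np.asarray(boneness.data, dtype=np.float64)
    if not np.isfinite(bje).all():
        raise ValueError("boneness map contains non-finite values")
    if roi is None:
        roi_arr = np.ones(bje.shape, dtype=bool)
    else:
        boneness.require_same_grid(roi, "ROI mask")
        roi_arr = roi.data
        if not roi_arr.any():
            raise ValueError("ROI is empty")

    terms = regional_terms(seeds, params)
    c_fg, c_bg = terms.label_costs(params)

    node_id = np.full(bje.shape, -1, dtype=np.int64)
    n = int(roi_arr.sum())
    node_id[roi_arr] = np.arange(n)
    # A foreground (source-side) voxel pays its severed sink link c_fg; a
    # background (sink-side) voxel pays its severed source link c_bg.
    src_cap = c_bg[roi_arr].astype(np.float64)
    snk_cap = c_fg[roi_arr].astype(np.float64)

    w = params.boundary_weight
    eu_parts, ev_parts, ecap_parts = [], [], []
    for off in _CONNECTIVITY_OFFSETS[params.connectivity]:
        sp, sq = _directed_pairs(bje.shape, off)
        in_p = roi_arr[sp]
        in_q = roi_arr[sq]
        both = in_p & in_q
        # Faces crossing the ROI boundary carry no penalty: the energy is
        # defined over the ROI subgraph only (the exterior is not part of
        # the problem, exactly as restricting Phase 2/3 to the body ROI).
        if both.any():
            u = node_id[sp][both]
            v = node_id[sq][both]
            bp = bje[sp][both]
            bq = bje[sq][both]
            eu_parts += [u, v]
            ev_parts += [v, u]
            ecap_parts += [w * boundary_term(bp, bq, params),
                           w * boundary_term(bq, bp, params)]

    if eu_parts:
        eu = np.concatenate(eu_parts)
        ev = np.concatenate(ev_parts)
        ecap = np.concatenate(ecap_parts)
    else:
        eu = ev = np.empty(0, dtype=np.int64)
        ecap = np.empty(0, dtype=np.float64)
    if not (np.isfinite(ecap).all() and np.isfinite(src_cap).all()
            and np.isfinite(snk_cap).all()):
        raise ValueError("non-finite graph capacities")

    solver = params.solver
    if solver == "auto":
        solver = "networkx" if n <= 2048 else "scipy"
    if solver == "networkx":
        fg_nodes = _solve_networkx(n, src_cap, snk_cap, eu, ev, ecap)
    else:
        fg_nodes = _solve_scipy(n, src_cap, snk_cap, eu, ev, ecap)

    fg = np.zeros(bje.shape, dtype=bool)
    fg[roi_arr] = fg_nodes

    if not seeds.foreground.any() and not fg.any():
        warnings.warn("empty segmentation (and no foreground seeds were given)",
                      RuntimeWarning, stacklevel=2)
    if params.keep_largest_component and fg.any():
        labels, ncomp = ndimage.label(fg)
        if ncomp > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            fg = labels == counts.argmax()
    return BinaryMask.like(boneness, fg)
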