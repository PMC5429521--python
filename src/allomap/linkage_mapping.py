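"""De novo linkage-map construction from classified loci.

Two-point recombination fractions are estimated by EM over the joint class
probabilities of a selfed heterozygote (an F2 design): each locus reduces
to the diploid genotype of its segregating subgenome, observed through a
codominant or dominant collapse.  Linkage groups are connected components
of the LOD/recombination-thresholded pair graph, orders minimize the sum of
adjacent recombination fractions (greedy insertion plus window-3 ripple),
and distances use Haldane's mapping function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic_data import CALL_CODES, MISSING, GenotypeMatrix

__all__ = [
    "PairStats",
    "LinkageGroup",
    "GeneticMap",
    "MARKER_TYPES",
    "marker_type_of",
    "estimate_r",
    "pairwise_stats",
    "convert_to_coupling",
    "group_loci",
    "order_group",
    "haldane_cm",
    "inverse_haldane",
    "impute_solitary_missing",
    "bin_loci",
    "attach_dominant_loci",
    "build_map",
]

LN10 = math.log(10.0)

# Observation collapse of the underlying diploid genotype (0=AA, 1=AB, 2=BB)
# of the segregating subgenome.
MARKER_TYPES: Dict[str, Tuple[int, int, int]] = {
    "codominant": (0, 1, 2),
    "dominant_AB_BB": (1, 1, 2),   # AA indistinguishable from AB
    "dominant_AB_AA": (0, 1, 1),   # BB indistinguishable from AB
}

_VARIANT_TO_TYPE = {
    "codominant_1_2_1": "codominant",
    "dominant_AB_BB_3_1": "dominant_AB_BB",
    "dominant_AB_AA_3_1": "dominant_AB_AA",
}


def marker_type_of(class_variant: str) -> Optional[str]:
    """Marker type usable for two-point estimation, or None."""
    return _VARIANT_TO_TYPE.get(class_variant)


@dataclass(frozen=True)
class PairStats:
    locus_a: str
    locus_b: str
    r_hat: float
    lod: float
    phase: str               # "coupling" or "repulsion"
    n_informative: int


@dataclass(frozen=True)
class LinkageGroup:
    id: str
    members: Tuple[str, ...]
    hg: Optional[str] = None


@lru_cache(maxsize=None)
def _coeff_tables(type_a: str, type_b: str, phase: str) -> Tuple[np.ndarray, ...]:
    """Counts of gamete-pair combinations producing each observed class pair.

    For a selfed double heterozygote, the four gamete haplotypes are two
    parental (each probability (1-r)/2) and two recombinant (each r/2);
    which pair is parental depends on phase.  Enumerating the 16 ordered
    gamete combinations and bucketing by the number of recombinant gametes
    (0, 1 or 2) gives integer coefficient tables (alpha, beta, gamma) over
    the 3x3 observed-class grid, so that

        16 * P(cell | r) = alpha*(1-r)^2 + beta*r*(1-r) + gamma*r^2.
    """
    if phase == "coupling":
        parental, recomb = [(0, 0), (1, 1)], [(0, 1), (1, 0)]
    elif phase == "repulsion":
        parental, recomb = [(0, 1), (1, 0)], [(0, 0), (1, 1)]
    else:
        raise ValueError(f"unknown phase {phase!r}")
    obs_a, obs_b = MARKER_TYPES[type_a], MARKER_TYPES[type_b]
    tables = [np.zeros((3, 3), dtype=float) for _ in range(3)]
    gametes = [(h, 0) for h in parental] + [(h, 1) for h in recomb]
    for h1, k1 in gametes:
        for h2, k2 in gametes:
            ga, gb = h1[0] + h2[0], h1[1] + h2[1]
            tables[k1 + k2][obs_a[ga], obs_b[gb]] += 1.0
    return tuple(t.ravel() for t in tables)


def _possible_cells(type_a: str, type_b: str) -> np.ndarray:
    a1, b1, c1 = _coeff_tables(type_a, type_b, "coupling")
    a2, b2, c2 = _coeff_tables(type_a, type_b, "repulsion")
    return (a1 + b1 + c1 + a2 + b2 + c2) > 0


def _em_r(counts: np.ndarray, alpha: np.ndarray, beta: np.ndarray,
          gamma: np.ndarray, tol: float = 1e-12, max_iter: int = 2000
          ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized EM for the recombination fraction of many pairs at once.

    ``counts`` is (P, 9); the E-step computes the expected number of
    recombinant gametes per observed cell, the M-step divides by 2N.
    Returns the estimates plus a per-pair convergence flag (EM converges
    only sublinearly when the maximum sits at the r = 0.5 boundary).
    """
    n2 = np.maximum(2.0 * counts.sum(axis=1), 1e-300)
    r = np.full(counts.shape[0], 0.25)
    converged = np.zeros(counts.shape[0], dtype=bool)
    for _ in range(max_iter):
        rm = 1.0 - r
        a = alpha[None, :] * (rm * rm)[:, None]
        b = beta[None, :] * (r * rm)[:, None]
        c = gamma[None, :] * (r * r)[:, None]
        denom = a + b + c
        safe = np.where(denom > 0, denom, 1.0)
        expected = (b + 2.0 * c) / safe
        r_new = (counts * expected).sum(axis=1) / n2
        np.clip(r_new, 1e-12, 0.5, out=r_new)
        converged |= np.abs(r_new - r) < tol
        r = r_new
        if converged.all():
            break
    return r, converged


def _polish_r(counts_row: np.ndarray, alpha: np.ndarray, beta: np.ndarray,
              gamma: np.ndarray) -> float:
    """Bounded scalar ML for a single stalled pair (EM fallback)."""
    from scipy.optimize import minimize_scalar

    def nll(r: float) -> float:
        return -float(_loglik(counts_row[None, :], alpha, beta, gamma,
                              np.array([r]))[0])

    res = minimize_scalar(nll, bounds=(0.0, 0.5), method="bounded",
                          options={"xatol": 1e-10})
    best_r = float(res.x)
    # the optimum may sit exactly on a boundary
    for edge in (0.0, 0.5):
        if nll(edge) <= nll(best_r):
            best_r = edge
    return best_r


def _loglik(counts: np.ndarray, alpha: np.ndarray, beta: np.ndarray,
            gamma: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood up to the constant -N*log(16)."""
    rm = 1.0 - r
    denom = (alpha[None, :] * (rm * rm)[:, None]
             + beta[None, :] * (r * rm)[:, None]
             + gamma[None, :] * (r * r)[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(np.where(denom > 0, denom, 1.0))
        logp[denom <= 0] = -np.inf
        terms = np.where(counts > 0, counts * logp, 0.0)
    return terms.sum(axis=1)


def _estimate_many(counts: np.ndarray, type_a: str, type_b: str
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(r, lod, phase_is_repulsion, n_informative) for a (P, 9) count block."""
    possible = _possible_cells(type_a, type_b)
    counts = counts * possible[None, :]
    n_informative = counts.sum(axis=1)

    results = {}
    for phase in ("coupling", "repulsion"):
        alpha, beta, gamma = _coeff_tables(type_a, type_b, phase)
        r, converged = _em_r(counts, alpha, beta, gamma)
        for i in np.flatnonzero(~converged):
            r[i] = _polish_r(counts[i], alpha, beta, gamma)
        ll = _loglik(counts, alpha, beta, gamma, r)
        ll_half = _loglik(counts, alpha, beta, gamma, np.full_like(r, 0.5))
        results[phase] = (r, ll, ll_half)
    rc, llc, llhc = results["coupling"]
    rr, llr, _ = results["repulsion"]
    repulsion = llr > llc + 1e-9
    r = np.where(repulsion, rr, rc)
    ll = np.where(repulsion, llr, llc)
    lod = np.maximum((ll - llhc) / LN10, 0.0)
    return np.clip(r, 0.0, 0.5), lod, repulsion, n_informative.astype(int)


def _cross_counts(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Joint call counts for every (row of a) x (row of b): (La, Lb, 9)."""
    ind_a = [(codes_a == u).astype(np.float64) for u in range(3)]
    ind_b = [(codes_b == v).astype(np.float64) for v in range(3)]
    la, lb = codes_a.shape[0], codes_b.shape[0]
    out = np.empty((la, lb, 9))
    for u in range(3):
        for v in range(3):
            out[:, :, 3 * u + v] = ind_a[u] @ ind_b[v].T
    return out


def _coerce_calls(calls) -> np.ndarray:
    arr = np.asarray(calls)
    if arr.dtype.kind in "OUS":
        codes = np.array([CALL_CODES.get(str(x), MISSING) for x in arr], dtype=np.int8)
        return codes
    return arr.astype(np.int8)


def estimate_r(calls_a, calls_b, class_a: str = "codominant",
               class_b: str = "codominant", locus_a: str = "a",
               locus_b: str = "b") -> PairStats:
    """Maximum-likelihood recombination fraction for one locus pair.

    ``calls_*`` are per-individual calls (codes or AA/AB/BB/NA strings);
    ``class_*`` name the marker types (see :data:`MARKER_TYPES`).  Both
    phases are evaluated and the better likelihood sets the phase.  Calls
    impossible under a dominant marker type are treated as uninformative.
    """
    if class_a not in MARKER_TYPES or class_b not in MARKER_TYPES:
        raise ValueError("marker classes must be keys of MARKER_TYPES")
    ca, cb = _coerce_calls(calls_a), _coerce_calls(calls_b)
    if ca.shape != cb.shape:
        raise ValueError("call vectors differ in length")
    counts = _cross_counts(ca[None, :], cb[None, :])[0, 0][None, :]
    r, lod, repulsion, n_inf = _estimate_many(counts, class_a, class_b)
    if n_inf[0] < 2:
        raise ValueError(
            f"pair ({locus_a}, {locus_b}) has {n_inf[0]} jointly informative "
            "individuals; need at least 2"
        )
    phase = "repulsion" if repulsion[0] else "coupling"
    return PairStats(locus_a, locus_b, float(r[0]), float(lod[0]), phase, int(n_inf[0]))


def pairwise_stats(matrix: GenotypeMatrix,
                   marker_types: Optional[Mapping[str, str]] = None,
                   loci: Optional[Sequence[str]] = None,
                   min_informative: int = 2) -> pd.DataFrame:
    """Two-point statistics for all locus pairs of ``matrix``.

    ``marker_types`` maps locus id to a :data:`MARKER_TYPES` key (default:
    everything codominant).  Pairs with fewer than ``min_informative``
    jointly scored individuals are dropped.  Returns a frame with columns
    ``a, b, r, lod, phase, n_informative`` (a < b lexicographically by
    matrix order).
    """
    loci = list(loci) if loci is not None else list(matrix.loci)
    idx = {l: matrix.locus_index(l) for l in loci}
    types = {l: (marker_types.get(l, "codominant") if marker_types else "codominant")
             for l in loci}
    by_type: Dict[str, List[str]] = {}
    for l in loci:
        by_type.setdefault(types[l], []).append(l)

    frames = []
    type_names = sorted(by_type)
    for i, ta in enumerate(type_names):
        for tb in type_names[i:]:
            la = by_type[ta]
            lb = by_type[tb]
            codes_a = matrix.calls[[idx[l] for l in la]]
            codes_b = matrix.calls[[idx[l] for l in lb]]
            counts = _cross_counts(codes_a, codes_b)
            if ta == tb:
                iu, ju = np.triu_indices(len(la), k=1)
                block = counts[iu, ju]
                names_a = [la[i_] for i_ in iu]
                names_b = [la[j_] for j_ in ju]
            else:
                iu, ju = np.meshgrid(np.arange(len(la)), np.arange(len(lb)),
                                     indexing="ij")
                iu, ju = iu.ravel(), ju.ravel()
                block = counts[iu, ju]
                names_a = [la[i_] for i_ in iu]
                names_b = [lb[j_] for j_ in ju]
            if block.shape[0] == 0:
                continue
            r, lod, repulsion, n_inf = _estimate_many(block, ta, tb)
            frames.append(pd.DataFrame({
                "a": names_a, "b": names_b, "r": r, "lod": lod,
                "phase": np.where(repulsion, "repulsion", "coupling"),
                "n_informative": n_inf,
                "type_a": ta, "type_b": tb,
            }))
    if not frames:
        return pd.DataFrame(columns=["a", "b", "r", "lod", "phase",
                                     "n_informative", "type_a", "type_b"])
    out = pd.concat(frames, ignore_index=True)
    return out[out["n_informative"] >= min_informative].reset_index(drop=True)


def haldane_cm(r: float, cap: bool = False) -> float:
    """Haldane map distance d = -50*ln(1-2r) in centimorgans.

    ``r >= 0.5`` raises unless ``cap`` is set, in which case r is capped
    just below 0.5 (configuration flag for saturated estimates).
    """
    if r < 0:
        raise ValueError(f"recombination fraction {r} < 0")
    if r >= 0.4999:
        if not cap:
            if r >= 0.5:
                raise ValueError(f"recombination fraction {r} >= 0.5")
        else:
            r = 0.4999
    return -50.0 * math.log(1.0 - 2.0 * r)


def inverse_haldane(d_cm: float) -> float:
    """Recombination fraction implied by a Haldane distance in cM."""
    if d_cm < 0:
        raise ValueError(f"negative map distance {d_cm}")
    return (1.0 - math.exp(-d_cm / 50.0)) / 2.0


def group_loci(pairs: pd.DataFrame, lod_threshold: float = 2.0,
               max_r: float = 0.4, loci: Optional[Sequence[str]] = None,
               exclude_dominant_repulsion: bool = True) -> List[LinkageGroup]:
    """Partition loci into linkage groups.

    Groups are connected components of the graph whose edges satisfy
    ``lod >= lod_threshold`` and ``r <= max_r``.  Dominant x dominant pairs
    in repulsion carry almost no linkage information in this design and are
    excluded from edges by default.  Group ids are deterministic: sorted by
    smallest member locus id.
    """
    if loci is None:
        loci = sorted(set(pairs["a"]) | set(pairs["b"]))
    graph = nx.Graph()
    graph.add_nodes_from(loci)
    sel = (pairs["lod"] >= lod_threshold) & (pairs["r"] <= max_r)
    if exclude_dominant_repulsion and {"type_a", "type_b", "phase"} <= set(pairs.columns):
        dd_rep = (pairs["type_a"].astype(str).str.startswith("dominant")
                  & pairs["type_b"].astype(str).str.startswith("dominant")
                  & (pairs["phase"] == "repulsion"))
        sel &= ~dd_rep
    for a, b in pairs.loc[sel, ["a", "b"]].itertuples(index=False):
        graph.add_edge(a, b)
    components = sorted((sorted(c) for c in nx.connected_components(graph)),
                        key=lambda c: c[0])
    return [LinkageGroup(id=f"G{i + 1}", members=tuple(c))
            for i, c in enumerate(components)]


def _r_matrix(members: Sequence[str], pairs: pd.DataFrame) -> np.ndarray:
    pos = {m: i for i, m in enumerate(members)}
    rmat = np.full((len(members), len(members)), 0.5)
    np.fill_diagonal(rmat, 0.0)
    sub = pairs[pairs["a"].isin(pos) & pairs["b"].isin(pos)]
    for a, b, r in sub[["a", "b", "r"]].itertuples(index=False):
        i, j = pos[a], pos[b]
        rmat[i, j] = rmat[j, i] = r
    return rmat


def _sarf(order: Sequence[int], rmat: np.ndarray) -> float:
    return float(sum(rmat[order[i], order[i + 1]] for i in range(len(order) - 1)))


def order_group(members: Sequence[str], pairs: pd.DataFrame,
                max_ripple_sweeps: int = 200) -> List[str]:
    """Order one linkage group by seriation.

    Greedy insertion: seed with the closest pair, then repeatedly place the
    unordered locus nearest to the ordered set at the position minimizing
    the sum of adjacent recombination fractions (SARF); afterwards, sweep a
    window of three with all local permutations (ripple) until no strict
    improvement remains.  Ties break by locus id, making the result
    deterministic up to overall orientation.
    """
    members = sorted(members)
    k = len(members)
    if k <= 2:
        return members
    rmat = _r_matrix(members, pairs)

    iu, ju = np.triu_indices(k, k=1)
    order_start = np.lexsort((ju, iu, rmat[iu, ju]))
    i0, j0 = int(iu[order_start[0]]), int(ju[order_start[0]])
    order = [i0, j0]
    remaining = sorted(set(range(k)) - {i0, j0})

    while remaining:
        nxt = min(remaining, key=lambda x: (rmat[x, order].min(), x))
        best_pos, best_delta = 0, math.inf
        for pos in range(len(order) + 1):
            if pos == 0:
                delta = rmat[nxt, order[0]]
            elif pos == len(order):
                delta = rmat[order[-1], nxt]
            else:
                a, b = order[pos - 1], order[pos]
                delta = rmat[a, nxt] + rmat[nxt, b] - rmat[a, b]
            if delta < best_delta - 1e-12:
                best_delta, best_pos = delta, pos
        order.insert(best_pos, nxt)
        remaining.remove(nxt)

    improved, sweeps = True, 0
    while improved and sweeps < max_ripple_sweeps:
        improved = False
        sweeps += 1
        for w in range(k - 2):
            window = order[w:w + 3]
            left = order[w - 1] if w > 0 else None
            right = order[w + 3] if w + 3 < k else None

            def local_cost(perm):
                cost = rmat[perm[0], perm[1]] + rmat[perm[1], perm[2]]
                if left is not None:
                    cost += rmat[left, perm[0]]
                if right is not None:
                    cost += rmat[perm[2], right]
                return cost

            current = local_cost(window)
            best_perm, best_cost = None, current
            for perm in permutations(window):
                cost = local_cost(perm)
                if cost < best_cost - 1e-12:
                    best_cost, best_perm = cost, perm
            if best_perm is not None:
                order[w:w + 3] = best_perm
                improved = True
    return [members[i] for i in order]


def convert_to_coupling(matrix: GenotypeMatrix,
                        phases: Mapping[str, str]) -> GenotypeMatrix:
    """Relabel loci in repulsion to their group seed: swap AA and BB calls.

    AB and missing calls are unchanged; applying the same conversion twice
    restores the original matrix.
    """
    out = matrix.copy()
    for locus, phase in phases.items():
        if phase == "repulsion":
            i = out.locus_index(locus)
            row = out.calls[i]
            out.calls[i] = np.where(row == 0, 2, np.where(row == 2, 0, row))
    return out


def _phases_from_seed(members: Sequence[str], pairs: pd.DataFrame,
                      seed: str) -> Dict[str, str]:
    """Phase of every group member relative to the seed locus, composed
    along the maximum-LOD spanning tree (repulsion flags XOR along paths)."""
    graph = nx.Graph()
    graph.add_nodes_from(members)
    member_set = set(members)
    sub = pairs[pairs["a"].isin(member_set) & pairs["b"].isin(member_set)]
    for a, b, lod, phase in sub[["a", "b", "lod", "phase"]].itertuples(index=False):
        graph.add_edge(a, b, lod=lod, repulsion=(phase == "repulsion"))
    tree = nx.maximum_spanning_tree(graph, weight="lod")
    phases = {m: "coupling" for m in members}
    for parent, child in nx.bfs_edges(tree, seed):
        flip = tree.edges[parent, child]["repulsion"]
        parent_rep = phases[parent] == "repulsion"
        phases[child] = "repulsion" if (parent_rep ^ flip) else "coupling"
    return phases


def bin_loci(matrix: GenotypeMatrix,
             groups: Sequence[LinkageGroup]) -> pd.Series:
    """Assign co-segregating loci to bins.

    Within each group, loci whose (coupling-converted) call vectors are
    identical on all jointly non-missing individuals — zero observed
    recombinants — share a bin; the relation is closed transitively.  The
    bin id is the lexicographically smallest member locus id.
    """
    assignment: Dict[str, str] = {}
    for group in groups:
        members = sorted(group.members)
        codes = np.stack([matrix.row(m) for m in members])
        k = len(members)
        graph = nx.Graph()
        graph.add_nodes_from(range(k))
        valid = codes >= 0
        for i in range(k):
            vi = valid[i]
            for j in range(i + 1, k):
                joint = vi & valid[j]
                if joint.any() and not (codes[i, joint] != codes[j, joint]).any():
                    graph.add_edge(i, j)
        for comp in nx.connected_components(graph):
            names = sorted(members[i] for i in comp)
            rep = names[0]
            for name in names:
                assignment[name] = rep
    return pd.Series(assignment, name="bin")


def impute_solitary_missing(matrix: GenotypeMatrix,
                            order: Mapping[str, Sequence[str]]) -> GenotypeMatrix:
    """Fill missing calls flanked by agreeing genotypes.

    ``order`` maps each linkage group id to its ordered locus list.  A
    missing call is imputed only when the nearest non-missing calls above
    and below it (same individual, same group) exist and agree; terminal
    loci therefore are never imputed, non-missing calls are never altered,
    and the operation is a fixed point of itself.
    """
    out = matrix.copy()
    for lg, loci in order.items():
        rows = [out.locus_index(l) for l in loci]
        codes = out.calls[rows]  # (L, N) view-copy
        l_count, n = codes.shape
        if l_count < 3:
            continue
        idx = np.arange(l_count)[:, None]
        valid = codes >= 0
        above_idx = np.where(valid, idx, -1)
        np.maximum.accumulate(above_idx, axis=0, out=above_idx)
        below_idx = np.where(valid, idx, l_count)
        below_idx = np.minimum.accumulate(below_idx[::-1], axis=0)[::-1]
        cols = np.arange(n)[None, :]
        above_val = np.where(above_idx >= 0,
                             codes[np.clip(above_idx, 0, None), cols], MISSING)
        below_val = np.where(below_idx < l_count,
                             codes[np.clip(below_idx, None, l_count - 1), cols],
                             MISSING)
        fill = ((codes == MISSING) & (above_val >= 0) & (below_val >= 0)
                & (above_val == below_val))
        codes = np.where(fill, above_val, codes).astype(np.int8)
        out.calls[rows] = codes
    return out


def _positions_from_order(ordered_bins: Sequence[str], rmat_lookup: Callable[[str, str], float],
                          r_cap: float = 0.4999) -> List[float]:
    positions = [0.0]
    for prev, cur in zip(ordered_bins, ordered_bins[1:]):
        r = min(max(rmat_lookup(prev, cur), 0.0), r_cap)
        positions.append(positions[-1] + haldane_cm(r, cap=True))
    return positions


def attach_dominant_loci(locus_table: pd.DataFrame, dominant: pd.DataFrame,
                         anchors: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Place dominant loci at the map position of the nearest anchored bin.

    ``dominant`` is a frame indexed by locus with a ``variant`` column;
    ``anchors`` maps locus -> (ref_chrom, ref_pos).  Each dominant locus
    with an anchor inherits the linkage group, position and bin of the
    mapped codominant locus whose anchor is physically nearest on the same
    reference chromosome (ties: smaller physical position, then locus id).
    Loci without anchors, or whose chromosome has no mapped loci, are
    returned in the unplaced list.
    """
    mapped = locus_table[~locus_table["attached"]].join(anchors, how="inner")
    unplaced: List[str] = []
    rows = []
    for locus in sorted(dominant.index):
        if locus not in anchors.index:
            unplaced.append(locus)
            continue
        chrom = anchors.at[locus, "ref_chrom"]
        pos = anchors.at[locus, "ref_pos"]
        cands = mapped[mapped["ref_chrom"] == chrom]
        if len(cands) == 0:
            unplaced.append(locus)
            continue
        cands = cands.sort_index()  # final tie-break: locus id (stable sort below)
        dist = (cands["ref_pos"] - pos).abs()
        best = cands.assign(_dist=dist).sort_values(
            by=["_dist", "ref_pos"], kind="mergesort"
        )
        target = best.iloc[0]
        rows.append({
            "locus": locus,
            "hg": target["hg"],
            "lg": target["lg"],
            "position_cm": target["position_cm"],
            "bin": target["bin"],
            "class": dominant.at[locus, "variant"] if "variant" in dominant.columns else "dominant",
            "phase": "",
            "attached": True,
        })
    if rows:
        extra = pd.DataFrame(rows).set_index("locus")
        locus_table = pd.concat([locus_table, extra])
    return locus_table, unplaced


@dataclass
class GeneticMap:
    """An ordered genetic map plus the converted genotype matrix behind it."""

    locus_table: pd.DataFrame     # index locus: hg, lg, position_cm, bin, class, phase, attached
    matrix: GenotypeMatrix        # coupling-converted (and imputed) codominant calls
    unplaced: List[str] = field(default_factory=list)

    def lg_order(self) -> Dict[str, List[str]]:
        """Ordered locus lists per linkage group (core loci only)."""
        core = self.locus_table[~self.locus_table["attached"]]
        out: Dict[str, List[str]] = {}
        for lg, sub in core.groupby("lg"):
            ordered = sub.sort_values(["position_cm"], kind="mergesort")
            out[str(lg)] = list(ordered.index)
        return out

    def lg_lengths(self) -> pd.Series:
        core = self.locus_table[~self.locus_table["attached"]]
        return core.groupby("lg")["position_cm"].max().rename("length_cm")

    def total_length(self) -> float:
        return float(self.lg_lengths().sum())

    def summary(self) -> pd.DataFrame:
        """Per-LG statistics: size, length, bins, class mix, mean bin span."""
        tab = self.locus_table
        rows = []
        for lg, sub in tab.groupby("lg"):
            core = sub[~sub["attached"]]
            n_bins = core["bin"].nunique()
            length = float(core["position_cm"].max()) if len(core) else math.nan
            rows.append({
                "lg": lg,
                "hg": core["hg"].iloc[0] if len(core) else "",
                "n_loci": len(sub),
                "n_codominant": int((sub["class"] == "codominant_1_2_1").sum()),
                "n_dominant": int(sub["class"].str.startswith("dominant").sum()),
                "n_bins": n_bins,
                "length_cm": length,
                "mean_bin_span_cm": length / (n_bins - 1) if n_bins > 1 else math.nan,
            })
        return pd.DataFrame(rows).set_index("lg")

    def to_tsv(self, path) -> None:
        self.locus_table.to_csv(path, sep="\t")


def build_map(
    matrix: GenotypeMatrix,
    classes: pd.DataFrame,
    anchors: Optional[pd.DataFrame] = None,
    lod_threshold: float = 2.0,
    max_r: float = 0.4,
    prepartition_by_anchor: Optional[bool] = None,
    impute: bool = True,
    attach_dominant: bool = True,
    min_informative: int = 2,
) -> GeneticMap:
    """Run the full mapping pipeline on a classified genotype matrix.

    Codominant 1:2:1 loci passing the classification filters are grouped
    (optionally pre-partitioned by the reference chromosome of their
    anchors), phase-converted to coupling, binned, ordered and assigned
    Haldane positions; solitary missing data are then imputed and the
    within-group statistics re-estimated for a second ordering round.
    Dominant loci are finally attached by nearest anchored physical
    position when anchors are available.
    """
    if prepartition_by_anchor is None:
        prepartition_by_anchor = anchors is not None

    codominant = classes[(classes["class"] == "codominant_1_2_1")
                         & classes["passes_filters"]]
    retained = [l for l in matrix.loci if l in codominant.index]

    partitions: Dict[str, List[str]] = {}
    if prepartition_by_anchor and anchors is not None:
        for locus in retained:
            key = str(anchors.at[locus, "ref_chrom"]) if locus in anchors.index else "~unanchored"
            partitions.setdefault(key, []).append(locus)
    else:
        partitions["all"] = retained

    work = matrix.subset(retained) if retained else matrix.subset([])
    records = []
    lg_counter = 0
    for part_key in sorted(partitions):
        part_loci = partitions[part_key]
        if not part_loci:
            continue
        pairs = pairwise_stats(work, loci=part_loci, min_informative=min_informative)
        groups = group_loci(pairs, lod_threshold, max_r, loci=part_loci)
        for group in groups:
            lg_counter += 1
            lg_id = f"LG{lg_counter:02d}"
            members = sorted(group.members)
            seed = members[0]
            phases = (_phases_from_seed(members, pairs, seed)
                      if len(members) > 1 else {seed: "coupling"})
            work = convert_to_coupling(work, phases)
            group_pairs = pairs

            for round_idx in range(2 if impute and len(members) > 2 else 1):
                bins = bin_loci(work, [group])
                reps = sorted(set(bins[m] for m in members))
                if len(reps) > 1:
                    ordered_reps = order_group(reps, group_pairs)
                else:
                    ordered_reps = reps
                lut = {(a, b): r for a, b, r in
                       group_pairs[["a", "b", "r"]].itertuples(index=False)}

                def r_of(x, y):
                    return lut.get((x, y), lut.get((y, x), 0.5))

                rep_pos = dict(zip(ordered_reps,
                                   _positions_from_order(ordered_reps, r_of)))
                if round_idx == 0 and impute and len(members) > 2:
                    ordered_loci = sorted(
                        members, key=lambda l: (rep_pos[bins[l]], l))
                    work = impute_solitary_missing(work, {lg_id: ordered_loci})
                    group_pairs = pairwise_stats(work, loci=members,
                                                 min_informative=min_informative)

            positions = {m: rep_pos[bins[m]] for m in members}
            # orient by anchors: physical position should increase with cM
            if anchors is not None:
                anch = [(positions[m], anchors.at[m, "ref_pos"])
                        for m in members if m in anchors.index]
                if len(anch) >= 3:
                    from scipy.stats import spearmanr
                    rho = spearmanr([a[0] for a in anch], [a[1] for a in anch]).statistic
                    if np.isfinite(rho) and rho < 0:
                        length = max(positions.values())
                        positions = {m: length - p for m, p in positions.items()}
            hg = ""
            if anchors is not None:
                chroms = [anchors.at[m, "ref_chrom"] for m in members
                          if m in anchors.index]
                if chroms:
                    hg = pd.Series(chroms).mode().iloc[0]
            for m in members:
                records.append({
                    "locus": m, "hg": hg, "lg": lg_id,
                    "position_cm": positions[m], "bin": bins[m],
                    "class": classes.at[m, "variant"],
                    "phase": phases[m], "attached": False,
                })

    if records:
        locus_table = pd.DataFrame(records).set_index("locus")
    else:
        locus_table = pd.DataFrame(
            columns=["hg", "lg", "position_cm", "bin", "class", "phase",
                     "attached"])
        locus_table.index.name = "locus"

    unplaced: List[str] = []
    if attach_dominant and anchors is not None:
        dominant = classes[classes["class"].str.startswith("dominant")
                           & classes["passes_filters"]]
        if len(dominant):
            locus_table, unplaced = attach_dominant_loci(locus_table, dominant,
                                                         anchors)
    return GeneticMap(locus_table, work, unplaced)
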