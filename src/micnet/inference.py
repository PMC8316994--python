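"""Edge-wise condition-vs-baseline statistics with FDR control.

The design is paired within participants: for each of the 231 electrode
pairs, the participant-wise difference d_k = cond_k - base_k between the
normalized connectivity values feeds a paired t statistic, whose null
distribution is built by sign-flipping the d_k (exact enumeration of all
2^n flips when n <= 12, Monte-Carlo otherwise).  Two-sided p-values are
adjusted by the Benjamini-Hochberg step-up procedure; edges with q below
alpha, ranked by q (ties broken by |t|), form the significance graph, and
the accompanying report mirrors the published table layout: index pair,
electrode names, hemisphere class, t, p, q and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from micnet.connectivity import ConnectivityMatrix
from micnet.graphstats import SignificanceGraph
from micnet.paradigm import Montage, classify_edge_hemisphere, standard_montage

__all__ = [
    "EdgeTestResult",
    "edgewise_permutation_ttest",
    "fdr_bh",
    "cohens_d",
    "significant_subgraph",
]


@dataclass(frozen=True)
class EdgeTestResult:
    """Statistics for one electrode pair's condition-vs-baseline contrast."""

    edge: tuple[int, int]
    t_stat: float
    p_perm: float
    q_fdr: float
    cohens_d: float
    direction: str  # 'increase' or 'decrease'


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Paired t statistics column-wise: d is participants x edges."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def _matrices_to_edge_array(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Stack per-participant matrices into participants x n_edges."""
    return np.stack([m.offdiag() for m in matrices])


def edgewise_permutation_ttest(
    cond: list[ConnectivityMatrix] | np.ndarray,
    base: list[ConnectivityMatrix] | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flip permutation paired t-test, one test per edge.

    ``cond`` and ``base`` are paired per-participant lists of connectivity
    matrices (or pre-stacked participants x edges arrays).  Returns
    ``(t_stat, p_perm)`` arrays over edges.  When the number of participants
    n <= 12 all 2^n sign patterns are enumerated and the p-value is exact;
    otherwise ``n_perm`` random flips give the Monte-Carlo p-value
    (1 + #{|t*| >= |t|}) / (1 + n_perm), never exactly zero.  Edges with
    zero-variance differences get p = 1 with a warning.
    """
    if not isinstance(cond, np.ndarray):
        cond = _matrices_to_edge_array(cond)
    if not isinstance(base, np.ndarray):
        base = _matrices_to_edge_array(base)
    if cond.shape != base.shape:
        raise ValueError(f"unpaired shapes {cond.shape} vs {base.shape}")
    n = cond.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 participants, have {n}")
    if n > 12 and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    d = cond - base  # participants x edges
    t_obs = _paired_t(d)

    zero_var = d.std(axis=0, ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} edge(s) with zero-variance differences; p set to 1",
            stacklevel=2,
        )

    # |t*| >= |t| comparison with a tiny tolerance so exact sign-symmetric
    # ties (t* = -t) are always counted.
    tol = 1e-12
    abs_obs = np.abs(t_obs)

    if n <= 12:
        signs = np.array(
            [[1 if (k >> b) & 1 == 0 else -1 for b in range(n)] for k in range(2**n)]
        )
        count = np.zeros(d.shape[1])
        for row in signs:
            t_null = _paired_t(row[:, None] * d)
            count += np.abs(t_null) >= abs_obs - tol
        p = count / 2**n
    else:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        count = np.zeros(d.shape[1])
        # Vectorized over flips in blocks to bound memory.
        block = max(1, int(2e7 // (n * d.shape[1] + 1)))
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            flips = rng.choice((-1.0, 1.0), size=(b, n))
            # (b, n) x (n, m) -> per-flip means; Var(flip*d) has the same
            # per-edge sum of squares, so t* follows from the flipped mean.
            m_null = flips @ d / n
            ssq = (d**2).sum(axis=0)
            var_null = (ssq - n * m_null**2) / (n - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_null = m_null / np.sqrt(var_null / n)
            count += (np.abs(t_null) >= abs_obs - tol).sum(axis=0)
            done += b
        p = (1.0 + count) / (1.0 + n_perm)

    t_out = np.where(zero_var, 0.0, t_obs)
    p = np.where(zero_var, 1.0, np.minimum(p, 1.0))
    return t_out, p


def fdr_bh(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort p ascending; q_(i) = min_{j >= i} p_(j) * m / j, capped at 1,
    mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def cohens_d(cond: np.ndarray, base: np.ndarray) -> float:
    """Paired Cohen's d: mean(differences) / sample sd (ddof=1).

    Returns NaN (flagged undefined) when the differences have zero sd.
    """
    cond = np.asarray(cond, dtype=float)
    base = np.asarray(base, dtype=float)
    if cond.shape != base.shape or cond.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = cond - base
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-sd differences; Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float(d.mean() / sd)


def _edge_list(n_channels: int) -> list[tuple[int, int]]:
    """Upper-triangle (i<j) 1-based edges in offdiag() order."""
    return [
        (i + 1, j + 1)
        for i in range(n_channels)
        for j in range(i + 1, n_channels)
    ]


def edge_test_results(
    cond: list[ConnectivityMatrix],
    base: list[ConnectivityMatrix],
    n_perm: int = 10_000,
    seed: int = 0,
    n_channels: int = 22,
) -> list[EdgeTestResult]:
    """Full per-edge contrast: t, permutation p, BH q, Cohen's d, direction."""
    cond_arr = _matrices_to_edge_array(cond)
    base_arr = _matrices_to_edge_array(base)
    t, p = edgewise_permutation_ttest(cond_arr, base_arr, n_perm=n_perm, seed=seed)
    q = fdr_bh(p)
    edges = _edge_list(n_channels)
    diffs = cond_arr - base_arr
    results = []
    for k, edge in enumerate(edges):
        sd = diffs[:, k].std(ddof=1)
        d_val = float(diffs[:, k].mean() / sd) if sd > 0 else float("nan")
        results.append(
            EdgeTestResult(
                edge=edge,
                t_stat=float(t[k]),
                p_perm=float(p[k]),
                q_fdr=float(q[k]),
                cohens_d=d_val,
                direction="decrease" if diffs[:, k].mean() < 0 else "increase",
            )
        )
    return results


def significant_subgraph(
    results: list[EdgeTestResult],
    alpha: float = 0.05,
    top_k: int | None = 19,
    montage: Montage | None = None,
) -> tuple[SignificanceGraph, pd.DataFrame]:
    """FDR-significant edges as a graph plus a published-table-style report.

    Edges with q < ``alpha`` are ranked by q ascending (|t| descending as
    tie-break) and truncated to ``top_k``.  The report lists index pair,
    electrode names, hemisphere class (strict both-endpoints rule), t, p, q
    and d, plus per-hemisphere counts in ``DataFrame.attrs``.
    """
    montage = montage or standard_montage()
    sig = [r for r in results if r.q_fdr < alpha]
    sig.sort(key=lambda r: (r.q_fdr, -abs(r.t_stat)))
    if top_k is not None:
        sig = sig[:top_k]
    edges = frozenset(r.edge for r in sig)
    graph = SignificanceGraph(n_vertices=len(montage), edges=edges)
    rows = []
    for r in sig:
        i, j = r.edge
        rows.append(
            {
                "electrode_pair_indices": f"ch{i}-ch{j}",
                "coherence_pair_names": f"{montage.name_of(i)}-{montage.name_of(j)}",
                "hemisphere": classify_edge_hemisphere(r.edge, montage),
                "t": r.t_stat,
                "p": r.p_perm,
                "q": r.q_fdr,
                "d": r.cohens_d,
                "direction": r.direction,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "electrode_pair_indices", "coherence_pair_names", "hemisphere",
            "t", "p", "q", "d", "direction",
        ],
    )
    counts = report["hemisphere"].value_counts().to_dict() if len(report) else {}
    report.attrs["hemisphere_counts"] = {
        side: int(counts.get(side, 0)) for side in ("left", "right", "bilateral")
    }
    return graph, report
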