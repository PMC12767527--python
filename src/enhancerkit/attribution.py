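"""Nucleotide contribution scores, motif scanning, and motif-level summaries.

Contribution scores are expected gradients: for each of ``n_refs``
dinucleotide-shuffled reference sequences, the model gradient is averaged
along the straight-line path from the reference to the input, yielding
per-position, per-base *hypothetical* scores whose projection onto the
observed one-hot sequence (*actual* scores) satisfies the completeness
identity sum(actual) ~= f(x) - mean_ref f(ref).

Dinucleotide shuffles preserve the exact dinucleotide count multiset of
the input (Eulerian-path construction), so the references keep the
input's local composition while destroying motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .sequences import one_hot, seq_to_codes, codes_to_seq

__all__ = [
    "dinucleotide_shuffle",
    "attribute",
    "AttributionMap",
    "pwm_from_consensus",
    "scan_motifs",
    "motif_contribution_table",
    "MotifContributionTable",
    "enrichment_test",
]


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul-Erickson Eulerian-path construction)


def dinucleotide_shuffle(sequence: str, n: int = 100, seed: int = 0) -> list[str]:
    """Return ``n`` shuffles preserving the exact dinucleotide count multiset.

    The sequence is viewed as an Eulerian trail on the 4-vertex base graph;
    each shuffle samples a random trail with the same edge multiset (random
    last-exit arborescence toward the terminal vertex, remaining edges
    shuffled).  Deterministic for a fixed seed.
    """
    codes = seq_to_codes(sequence)
    if len(codes) < 2:
        raise ValueError("sequence must be at least 2 nt")
    if (codes > 3).any():
        raise ValueError("sequence must contain only ACGT")
    rng = np.random.default_rng(seed)

    # adjacency: for each vertex, the multiset of successor vertices
    successors: dict[int, list[int]] = {}
    for a, b in zip(codes[:-1], codes[1:]):
        successors.setdefault(int(a), []).append(int(b))
    vertices = sorted(set(int(c) for c in codes))
    first, last = int(codes[0]), int(codes[-1])
    if len(vertices) == 1:
        warnings.warn("single-base sequence has a unique shuffle", stacklevel=2)
        return [sequence] * n

    non_terminal = [v for v in vertices if v != last and successors.get(v)]
    out = []
    for _ in range(n):
        # sample last-exit edges forming an arborescence toward `last`
        while True:
            last_exit = {v: successors[v][rng.integers(len(successors[v]))] for v in non_terminal}
            ok = True
            for v in non_terminal:
                seen, cur = {v}, v
                while cur != last:
                    cur = last_exit.get(cur)
                    if cur is None or cur in seen:
                        ok = False
                        break
                    seen.add(cur)
                if not ok:
                    break
            if ok:
                break
        # shuffle the remaining edges and append the reserved last-exit edge
        pools: dict[int, list[int]] = {}
        for v in vertices:
            edges = list(successors.get(v, []))
            if v in last_exit:
                edges.remove(last_exit[v])
            rng.shuffle(edges)
            if v in last_exit:
                edges.append(last_exit[v])
            pools[v] = edges
        walk = [first]
        ptr = {v: 0 for v in vertices}
        cur = first
        for _step in range(len(codes) - 1):
            nxt = pools[cur][ptr[cur]]
            ptr[cur] += 1
            walk.append(nxt)
            cur = nxt
        out.append(codes_to_seq(np.array(walk, dtype=np.uint8)))
    return out


# ---------------------------------------------------------------------------
# expected-gradient attributions


@dataclass
class AttributionMap:
    """Per-position contribution scores for one sequence."""

    sequence: str
    hypothetical: np.ndarray  # (L, 4)
    actual: np.ndarray  # (L,) = row-wise dot of hypothetical with one-hot
    n_references: int
    prediction: float  # raw model output f(x)
    reference_mean: float  # mean_ref f(ref)
    model_info: dict = field(default_factory=dict)

    @property
    def completeness_gap(self) -> float:
        """|sum(actual) - (f(x) - mean f(ref))| relative to the difference."""
        diff = self.prediction - self.reference_mean
        return abs(self.actual.sum() - diff) / max(abs(diff), 1e-8)


def attribute(
    ensemble,
    sequence: str,
    n_refs: int = 100,
    seed: int = 0,
    steps: int = 20,
    batch_size: int = 256,
) -> AttributionMap:
    """Expected-gradient contribution scores against dinucleotide-shuffled
    references, averaged over the ensemble members.

    ``ensemble`` needs ``members`` with ``forward``/``input_gradient``
    semantics (a :class:`~enhancerkit.models.ModelEnsemble`); gradients are
    taken on the raw (pre-sigmoid) output.  Only the forward-strand sequence
    is attributed.
    """
    length = getattr(ensemble.members[0], "spec", None)
    expected_len = length.input_length if length is not None else None
    if expected_len is not None and len(sequence) != expected_len:
        raise ValueError(f"sequence must be {expected_len} nt, got {len(sequence)}")

    x = one_hot(sequence)  # (L, 4)
    refs = np.stack([one_hot(s) for s in dinucleotide_shuffle(sequence, n=n_refs, seed=seed)])
    # interpolation points: ref + t (x - ref), midpoint rule
    ts = (np.arange(steps) + 0.5) / steps
    inputs = refs[:, None] + ts[None, :, None, None] * (x[None, None] - refs[:, None])
    inputs = inputs.reshape(n_refs * steps, *x.shape).astype(np.float32)

    hyp_members = []
    pred_members, refmean_members = [], []
    for member in ensemble.members:
        grads = np.concatenate(
            [member.input_gradient(inputs[i : i + batch_size]) for i in range(0, len(inputs), batch_size)]
        )
        avg_grad = grads.reshape(n_refs, steps, *x.shape).mean(axis=1)  # (n_refs, L, 4)
        # per-reference hypothetical: gradient minus its projection onto the
        # reference base at each position (so actual = (x - ref) . avg_grad)
        proj = (avg_grad * refs).sum(axis=2, keepdims=True)
        hyp_members.append((avg_grad - proj).mean(axis=0))
        pred_members.append(member.predict(x[None], output="logit")[0])
        refmean_members.append(member.predict(refs, output="logit").mean())

    hypothetical = np.mean(hyp_members, axis=0)
    actual = (hypothetical * x).sum(axis=1)
    return AttributionMap(
        sequence=sequence,
        hypothetical=hypothetical.astype(np.float64),
        actual=actual.astype(np.float64),
        n_references=n_refs,
        prediction=float(np.mean(pred_members)),
        reference_mean=float(np.mean(refmean_members)),
        model_info={"task": getattr(ensemble, "task", None), "tissue": getattr(ensemble, "tissue", None),
                    "n_members": len(ensemble.members), "steps": steps},
    )


# ---------------------------------------------------------------------------
# PWM scanning with exact p-value thresholds


def pwm_from_consensus(consensus: str, p_consensus: float = 0.97) -> np.ndarray:
    """Near-degenerate position probability matrix for a consensus string."""
    mat = np.full((len(consensus), 4), (1.0 - p_consensus) / 3.0)
    codes = seq_to_codes(consensus)
    mat[np.arange(len(consensus)), codes] = p_consensus
    return mat


def _pwm_threshold(int_scores: np.ndarray, background: np.ndarray, p_cutoff: float) -> int:
    """Smallest integer threshold T with P(score >= T | background) <= p_cutoff.

    Exact dynamic programming over the discretized per-position score
    distribution (convolution of four-spike pmfs).
    """
    w = int_scores.shape[0]
    cur = np.array([1.0])  # pmf over score sums, support starts at cur_offset
    cur_offset = 0
    for i in range(w):
        lo_i = int(int_scores[i].min())
        hi_i = int(int_scores[i].max())
        new = np.zeros(len(cur) + hi_i - lo_i)
        for b in range(4):
            s = int(int_scores[i, b])
            new[s - lo_i : s - lo_i + len(cur)] += background[b] * cur
        cur = new
        cur_offset += lo_i
    tail = np.cumsum(cur[::-1])[::-1]
    meets = np.flatnonzero(tail <= p_cutoff)
    if len(meets) == 0:
        return cur_offset + len(cur)  # unreachable threshold
    return cur_offset + int(meets[0])


def scan_motifs(
    sequences: dict[str, str],
    pwms: dict[str, np.ndarray],
    p_cutoff: float = 5e-5,
    pseudocount: float = 1e-3,
    background: np.ndarray | None = None,
    scale: float = 100.0,
) -> pd.DataFrame:
    """Log-odds PWM scan on both strands with exact p-value thresholds.

    The background is estimated from the scanned sequences themselves
    unless given.  Scores are log2 odds discretized at 1/``scale``; the
    per-PWM threshold is the smallest score whose exceedance probability
    under the background (exact DP) is <= ``p_cutoff``.
    Returns columns: seq_id, start, end, strand, pwm_id, score.
    """
    seq_codes = {sid: seq_to_codes(s) for sid, s in sequences.items()}
    if background is None:
        all_codes = np.concatenate(list(seq_codes.values()))
        all_codes = all_codes[all_codes < 4]
        background = np.bincount(all_codes, minlength=4) / len(all_codes)
    background = np.asarray(background, dtype=float)

    rows = []
    for pwm_id, pwm in pwms.items():
        pwm = np.asarray(pwm, dtype=float)
        if (pwm.sum(axis=1) <= 0).any():
            raise ValueError(f"PWM {pwm_id!r} has a zero column sum")
        probs = pwm + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        logodds = np.log2(probs / background)
        int_scores = np.rint(logodds * scale).astype(int)
        thr = _pwm_threshold(int_scores, background, p_cutoff)
        w = pwm.shape[0]
        rc_scores = int_scores[::-1, ::-1]  # scan RC of PWM on the forward strand
        for sid, codes in seq_codes.items():
            if len(codes) < w or (codes > 3).any():
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, w)
            pos_idx = np.arange(w)
            fwd = int_scores[pos_idx, windows].sum(axis=1)
            rev = rc_scores[pos_idx, windows].sum(axis=1)
            for start in np.flatnonzero(fwd >= thr):
                rows.append((sid, int(start), int(start) + w, "+", pwm_id, fwd[start] / scale))
            for start in np.flatnonzero(rev >= thr):
                rows.append((sid, int(start), int(start) + w, "-", pwm_id, rev[start] / scale))
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand", "pwm_id", "score"])


# ---------------------------------------------------------------------------
# motif contribution table


@dataclass
class MotifContributionTable:
    """Per-PWM contribution z-scores and the 4-way cluster structure."""

    table: pd.DataFrame  # index pwm_id; z_<task>_<tissue> columns, max_z, retained
    retained: pd.DataFrame  # representatives after filtering, clipped, with cluster id
    dropped_pwms: list[str]


def motif_contribution_table(
    instances: pd.DataFrame,
    actual_scores: dict[str, dict[str, dict[str, np.ndarray]]],
    z_min: float = 2.0,
    redundancy_groups: dict[str, str] | None = None,
    n_clusters: int = 4,
    clip_percentiles: tuple[float, float] = (5.0, 95.0),
) -> MotifContributionTable:
    """Aggregate per-instance contribution scores to per-PWM z-scores.

    ``instances``: motif hits (seq_id, start, end, pwm_id) from
    :func:`scan_motifs`.  ``actual_scores[task][tissue][seq_id]`` is the
    per-position actual contribution vector of that sequence under that
    task/tissue model.  Pipeline: per-instance mean -> per-PWM mean ->
    z-score across PWMs per (task, tissue); keep PWMs with max z >= z_min;
    one representative per redundancy group (highest z); clip to the given
    percentiles per column; complete-linkage hierarchical clustering on
    Euclidean distances, cut into ``n_clusters``.
    """
    columns = [(task, tissue) for task in actual_scores for tissue in actual_scores[task]]
    pwm_ids = sorted(instances["pwm_id"].unique())
    means = pd.DataFrame(index=pwm_ids, columns=[f"z_{t}_{u}" for t, u in columns], dtype=float)
    dropped = []
    for task, tissue in columns:
        scores = actual_scores[task][tissue]
        col = f"z_{task}_{tissue}"
        per_pwm: dict[str, list[float]] = {p: [] for p in pwm_ids}
        for row in instances.itertuples(index=False):
            vec = scores.get(row.seq_id)
            if vec is None:
                continue
            per_pwm[row.pwm_id].append(float(np.mean(vec[row.start : row.end])))
        means[col] = [np.mean(v) if v else np.nan for p, v in ((p, per_pwm[p]) for p in pwm_ids)]
    has_any = means.notna().all(axis=1)
    dropped = list(means.index[~has_any])
    means = means[has_any]
    # z-score across the full PWM set, per column (before any filtering);
    # a degenerate all-equal column gets z = 0 everywhere
    std = means.std(ddof=0).replace(0.0, 1.0)
    z = (means - means.mean()) / std
    z["max_z"] = z.max(axis=1)
    z["retained"] = z["max_z"] >= z_min

    groups = redundancy_groups or {p: p for p in z.index}
    retained = z[z["retained"]].copy()
    retained["group"] = [groups.get(p, p) for p in retained.index]
    reps = retained.sort_values("max_z", ascending=False).groupby("group").head(1)
    value_cols = [c for c in reps.columns if c.startswith("z_")]
    clipped = reps[value_cols].copy()
    if len(clipped):
        for c in value_cols:
            lo, hi = np.percentile(clipped[c], clip_percentiles)
            clipped[c] = clipped[c].clip(lo, hi)
    if len(clipped) >= 2:
        link = linkage(clipped.to_numpy(), method="complete", metric="euclidean")
        clusters = fcluster(link, t=min(n_clusters, len(clipped)), criterion="maxclust")
    else:
        clusters = np.ones(len(clipped), dtype=int)
    result = clipped.copy()
    result["cluster"] = clusters
    result["max_z"] = reps["max_z"]
    return MotifContributionTable(table=z, retained=result, dropped_pwms=dropped)


# ---------------------------------------------------------------------------
# TF-set enrichment


def enrichment_test(
    cluster_members: dict[str, set],
    category_sets: dict[str, set],
    background: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact test of each (cluster, category) pair over a common
    TF background, with Benjamini-Hochberg FDR across all tests."""
    if not background:
        raise ValueError("background set is empty")
    rows = []
    for cname, cluster in cluster_members.items():
        if not cluster <= background:
            raise ValueError(f"cluster {cname!r} not contained in background")
        for gname, category in category_sets.items():
            cat = category & background
            a = len(cluster & cat)
            b = len(cluster - cat)
            c = len(cat - cluster)
            d = len(background) - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((cname, gname, a, b, c, d, odds, p))
    df = pd.DataFrame(rows, columns=["cluster", "category", "a", "b", "c", "d", "odds_ratio", "p_value"])
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["fdr"] < alpha
    return df
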