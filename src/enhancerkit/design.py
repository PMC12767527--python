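"""Gradient-based design of tissue-specific synthetic enhancers.

Starting from random seed sequences with dinucleotide frequencies matched
to a reference set, a continuous relaxation of the one-hot input is
optimized to push both the accessibility model and the activity model
(pre-sigmoid logits, to avoid gradient saturation) toward high target
values, with a penalty on deviations from the seed that keeps the number
of edits small.  Designs are then filtered for tissue specificity (high
target-tissue logit, sub-zero off-target logits) and genome novelty
(exact k-mer screen, with external BLAST as an optional stricter check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome
from .sequences import dinucleotide_counts, one_hot, seq_to_codes, codes_to_seq

DEFAULT_SELECTION_THRESHOLDS = {"heart": 6.0, "limb": 5.0, "midbrain": 7.0}


@dataclass
class DesignConfig:
    n_seeds: int = 1200
    edit_penalty: float = 0.1  # weight of the deviation-from-seed penalty
    target_accessibility: float = 12.0
    target_activity_logit: float = 14.0
    max_iterations: int = 500
    learning_rate: float = 0.1
    plateau_patience: int = 20
    selection_thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SELECTION_THRESHOLDS))
    offtarget_max_logit: float = 0.0

    def __post_init__(self):
        if self.edit_penalty < 0:
            raise ValueError("edit_penalty must be >= 0")
        if not (np.isfinite(self.target_accessibility) and np.isfinite(self.target_activity_logit)):
            raise ValueError("targets must be finite")


@dataclass
class DesignedSequence:
    sequence: str
    seed_id: str
    seed_sequence: str
    target_tissue: str
    n_edits: int  # Hamming distance to the seed
    accessibility: float  # predicted accessibility in the target tissue
    activity_logit: float  # predicted activity logit in the target tissue
    seed_accessibility: float
    seed_activity_logit: float
    improved: bool  # False -> optimizer failed to beat the seed; sequence == seed
    activity_logits: dict[str, float] = field(default_factory=dict)  # per-tissue, filled by score_designs
    selected: bool | None = None
    novel: bool | None = None
    offending_kmer: str | None = None


def sample_seeds(
    reference_sequences: list[str],
    n: int = 1200,
    length: int = 1001,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> list[str]:
    """Random sequences from a first-order Markov chain matched to the
    pooled dinucleotide frequencies of the reference set."""
    if not reference_sequences:
        raise ValueError("reference set is empty")
    counts = sum(dinucleotide_counts(s) for s in reference_sequences).astype(float)
    zero_rows = counts.sum(axis=1) == 0
    if zero_rows.any():
        warnings.warn("reference lacks some dinucleotides; smoothing with pseudocount", stacklevel=2)
        counts[zero_rows] += pseudocount
    trans = counts / counts.sum(axis=1, keepdims=True)
    marginal = counts.sum(axis=1) / counts.sum()

    rng = np.random.default_rng(seed)
    cum_trans = trans.cumsum(axis=1)
    state = np.searchsorted(marginal.cumsum(), rng.random(n), side="right").clip(0, 3)
    seqs = np.empty((n, length), dtype=np.uint8)
    seqs[:, 0] = state
    for pos in range(1, length):
        u = rng.random(n)
        state = (cum_trans[state] < u[:, None]).sum(axis=1).clip(0, 3).astype(np.uint8)
        seqs[:, pos] = state
    return [codes_to_seq(row) for row in seqs]


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def design_sequence(
    seed_sequence: str,
    models: dict,
    cfg: DesignConfig,
    target_tissue: str = "",
    seed_id: str = "seed",
) -> DesignedSequence:
    """Optimize one seed against the accessibility and activity models.

    ``models`` maps ``"accessibility"`` and ``"activity"`` to objects with a
    ``value_and_grad(x) -> (float, (L, 4) array)`` contract evaluated on raw
    (pre-sigmoid) outputs.  The loss is

        (f_acc(x) - t_acc)^2 + (f_act(x) - t_act)^2 + lambda * D(x, seed)

    where x is the softmax of unconstrained per-position logits and D is the
    categorical cross-entropy between x and the seed one-hot.  The returned
    sequence is the per-position argmax at the best-loss iterate; if it does
    not beat the seed on *both* models, the seed itself is returned with
    ``improved=False``.
    """
    seed_oh = one_hot(seed_sequence)
    length = len(seed_sequence)
    m_acc, m_act = models["accessibility"], models["activity"]

    def discrete_scores(oh):
        return m_acc.value_and_grad(oh)[0], m_act.value_and_grad(oh)[0]

    seed_acc, seed_act = discrete_scores(seed_oh)

    z = (seed_oh * 8.0).astype(np.float64)  # sharp but finite initialization
    mom = np.zeros_like(z)
    vel = np.zeros_like(z)
    best_loss, best_z, wait = np.inf, z.copy(), 0
    t = 0
    for _it in range(cfg.max_iterations):
        x = _softmax(z)
        fa, ga = m_acc.value_and_grad(x.astype(np.float32))
        fc, gc = m_act.value_and_grad(x.astype(np.float32))
        if not (np.isfinite(ga).all() and np.isfinite(gc).all()):
            raise FloatingPointError(f"non-finite gradients at iteration {_it} for {seed_id}")
        edit = -(seed_oh * np.log(np.maximum(x, 1e-12))).sum()
        loss = (fa - cfg.target_accessibility) ** 2 + (fc - cfg.target_activity_logit) ** 2 + cfg.edit_penalty * edit
        if loss < best_loss - 1e-9:
            best_loss, best_z, wait = loss, z.copy(), 0
        else:
            wait += 1
            if wait >= cfg.plateau_patience:
                break
        dx = 2 * (fa - cfg.target_accessibility) * ga + 2 * (fc - cfg.target_activity_logit) * gc
        dx = dx - cfg.edit_penalty * seed_oh / np.maximum(x, 1e-12)
        # backprop through per-position softmax
        dz = x * (dx - (dx * x).sum(axis=1, keepdims=True))
        t += 1
        mom = 0.9 * mom + 0.1 * dz
        vel = 0.999 * vel + 0.001 * dz * dz
        z -= cfg.learning_rate * (mom / (1 - 0.9**t)) / (np.sqrt(vel / (1 - 0.999**t)) + 1e-7)

    final_codes = best_z.argmax(axis=1).astype(np.uint8)
    final_seq = codes_to_seq(final_codes)
    final_oh = one_hot(final_seq)
    acc, act = discrete_scores(final_oh)
    if acc >= seed_acc and act >= seed_act:
        n_edits = int((final_codes != seq_to_codes(seed_sequence)).sum())
        return DesignedSequence(
            sequence=final_seq, seed_id=seed_id, seed_sequence=seed_sequence, target_tissue=target_tissue,
            n_edits=n_edits, accessibility=acc, activity_logit=act,
            seed_accessibility=seed_acc, seed_activity_logit=seed_act, improved=True,
        )
    return DesignedSequence(
        sequence=seed_sequence, seed_id=seed_id, seed_sequence=seed_sequence, target_tissue=target_tissue,
        n_edits=0, accessibility=seed_acc, activity_logit=seed_act,
        seed_accessibility=seed_acc, seed_activity_logit=seed_act, improved=False,
    )


def score_designs(designs: list[DesignedSequence], activity_models: dict[str, object]) -> None:
    """Fill per-tissue activity logits (in place) for specificity selection."""
    if not designs:
        return
    X = np.stack([one_hot(d.sequence) for d in designs])
    for tissue, model in activity_models.items():
        logits = model.predict(X, output="logit")
        for d, v in zip(designs, logits):
            d.activity_logits[tissue] = float(v)


def select_candidates(
    designs: list[DesignedSequence], cfg: DesignConfig
) -> tuple[list[DesignedSequence], dict[str, int]]:
    """Keep designs with target-tissue logit above its per-tissue threshold
    and every off-target logit below ``cfg.offtarget_max_logit``."""
    selected = []
    counts: dict[str, int] = {}
    for d in designs:
        if not d.activity_logits:
            raise ValueError(f"design {d.seed_id} has no per-tissue activity logits")
        missing = [t for t in list(cfg.selection_thresholds) if t not in d.activity_logits]
        if missing:
            raise ValueError(f"design {d.seed_id} lacks predictions for {missing}")
        thr = cfg.selection_thresholds[d.target_tissue]
        on = d.activity_logits[d.target_tissue] > thr
        off = all(
            v < cfg.offtarget_max_logit for t, v in d.activity_logits.items() if t != d.target_tissue
        )
        d.selected = bool(on and off)
        if d.selected:
            selected.append(d)
            counts[d.target_tissue] = counts.get(d.target_tissue, 0) + 1
    return selected, counts


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a code array into an int64 (N-containing skipped)."""
    if len(codes) < k:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid].astype(np.int64) @ powers


def genome_kmer_set(genomes: list[Genome], k: int) -> np.ndarray:
    """All k-mers present in the genomes, both strands, as a sorted array
    of packed integers (kept as an array, not a set, to stay memory-lean
    for megabase genomes)."""
    from .sequences import reverse_complement_codes

    parts = []
    for genome in genomes:
        for chrom in genome.names:
            codes = genome.chroms[chrom]
            for strand_codes in (codes, reverse_complement_codes(codes)):
                for start in range(0, len(strand_codes), 500_000):
                    chunk = strand_codes[max(0, start - k + 1) : start + 500_000]
                    parts.append(_kmer_codes(chunk, k))
    if not parts:
        return np.zeros(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def novelty_screen(
    designs: list[DesignedSequence],
    genomes: list[Genome] | Genome,
    k: int = 24,
    kmer_set: np.ndarray | None = None,
) -> list[DesignedSequence]:
    """Exact k-mer novelty screen: a design fails if any of its k-mers occurs
    in any genome (either strand).  Updates and returns the designs.

    With k=24, a random 1,001-mer against a desk-scale genome collides with
    probability ~ L_design * L_genome / 4^24, i.e. essentially never, so the
    screen only rejects genuine copies.  An external BLAST search can be
    layered on top for production use.
    """
    if isinstance(genomes, Genome):
        genomes = [genomes]
    for d in designs:
        if k > len(d.sequence):
            raise ValueError(f"k={k} exceeds design length {len(d.sequence)}")
    if kmer_set is None:
        kmer_set = genome_kmer_set(genomes, k)
    if len(kmer_set) == 0:
        for d in designs:
            d.novel, d.offending_kmer = True, None
        return designs
    for d in designs:
        packed = _kmer_codes(seq_to_codes(d.sequence), k)
        pos = np.searchsorted(kmer_set, packed)
        present = (pos < len(kmer_set)) & (kmer_set[np.minimum(pos, len(kmer_set) - 1)] == packed)
        hits = np.flatnonzero(present)
        if len(hits) == 0:
            d.novel, d.offending_kmer = True, None
        else:
            d.novel, d.offending_kmer = False, d.sequence[int(hits[0]) : int(hits[0]) + k]
    return designs


def designs_to_frame(designs: list[DesignedSequence], tissues: list[str]) -> pd.DataFrame:
    rows = []
    for d in designs:
        row = {
            "seed_id": d.seed_id, "target_tissue": d.target_tissue, "sequence": d.sequence,
            "n_edits": d.n_edits, "accessibility": d.accessibility, "activity_logit": d.activity_logit,
            "seed_accessibility": d.seed_accessibility, "seed_activity_logit": d.seed_activity_logit,
            "improved": d.improved, "selected": d.selected, "novel": d.novel,
        }
        for t in tissues:
            row[f"logit_{t}"] = d.activity_logits.get(t, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
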