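"""Synthetic multi-tissue regulatory genome with known ground truth.

The generator emulates the structure of the real training inputs — a genome,
per-tissue accessibility tracks, peak calls, and a table of validated
enhancers with per-tissue activity bits — but with a fully known motif
grammar: each tissue has its own set of consensus motifs, regions carry
``k`` planted instances, accessibility grows linearly with ``k``
(``baseline + signal_gain * k``, log-normal noise on top), and a region is
an active enhancer in a tissue iff it carries at least ``activity_rule``
instances of that tissue's motifs.  Shared motifs count toward every
tissue, giving rise to multi-tissue ("globally open") regions.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome
from .sequences import reverse_complement, seq_to_codes
from .tracks import SignalTrack

DEFAULT_TISSUES = ["heart", "limb", "midbrain"]

# one consensus motif per tissue; 8-mers are long enough that chance
# occurrences in ~1 kb windows are rare (~0.03 expected incl. both strands),
# and a single motif per tissue keeps each planted pattern frequent enough
# for a compact CNN to discover from a few hundred regions
DEFAULT_MOTIFS = {
    "heart": ["CTAAATAG"],
    "limb": ["CAGATGGC"],
    "midbrain": ["CAACAATG"],
}
DEFAULT_SHARED = ["ATGCAAAT"]

# accessibility-only motif (broadly bound, e.g. insulator/pioneer-like):
# raises the accessibility signal in every tissue but never confers in vivo
# enhancer activity — the "open but inactive" region class that separates
# the accessibility and activity tasks
DEFAULT_ACCESSIBILITY_ONLY = ["CCGGAAGT"]

REGION_LENGTH = 1001
MIN_GAP = 1500


class CapacityError(RuntimeError):
    """The genome cannot host the requested regions at the required spacing."""


@dataclass
class MotifGrammar:
    """The ground-truth regulatory grammar the synthetic genome obeys."""

    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    motifs_per_tissue: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MOTIFS.items()})
    shared_motifs: list[str] = field(default_factory=lambda: list(DEFAULT_SHARED))
    accessibility_motifs: list[str] = field(default_factory=lambda: list(DEFAULT_ACCESSIBILITY_ONLY))
    activity_rule: int = 2  # min. motif count for a region to be active
    signal_gain: float = 2.0  # accessibility units per planted motif
    noise_sd: float = 0.3  # sd of Gaussian noise on the log signal
    baseline: float = 1.0  # accessibility of motif-free regions

    def __post_init__(self) -> None:
        if self.activity_rule < 1:
            raise ValueError("activity_rule must be >= 1")
        seen: dict[str, str] = {}
        for tissue in self.tissues:
            if tissue not in self.motifs_per_tissue:
                raise ValueError(f"no motifs defined for tissue {tissue!r}")
        for owner, motifs in (
            list(self.motifs_per_tissue.items())
            + [("shared", self.shared_motifs), ("open", self.accessibility_motifs)]
        ):
            for m in motifs:
                if not m or set(m) - set("ACGT"):
                    raise ValueError(f"motif {m!r} is not a non-empty ACGT string")
                if not 6 <= len(m) <= 10:
                    raise ValueError(f"motif {m!r} must be 6-10 nt long")
                if m in seen and seen[m] != owner:
                    raise ValueError(f"motif {m!r} appears in both {seen[m]} and {owner}")
                seen[m] = owner

    def all_motifs(self) -> dict[str, tuple[str, str]]:
        """motif_id -> (consensus, owner: a tissue, 'shared', or 'open')."""
        out = {}
        for tissue in self.tissues:
            for i, m in enumerate(self.motifs_per_tissue[tissue]):
                out[f"{tissue}_{i}"] = (m, tissue)
        for i, m in enumerate(self.shared_motifs):
            out[f"shared_{i}"] = (m, "shared")
        for i, m in enumerate(self.accessibility_motifs):
            out[f"open_{i}"] = (m, "open")
        return out

    def to_dict(self) -> dict:
        return {
            "tissues": self.tissues,
            "motifs_per_tissue": self.motifs_per_tissue,
            "shared_motifs": self.shared_motifs,
            "accessibility_motifs": self.accessibility_motifs,
            "activity_rule": self.activity_rule,
            "signal_gain": self.signal_gain,
            "noise_sd": self.noise_sd,
            "baseline": self.baseline,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifGrammar":
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted where, and the labels/signals that follow from it."""

    grammar: MotifGrammar
    regions: pd.DataFrame  # region_id, chrom, start, end, kind
    planted_instances: pd.DataFrame  # chrom, start, end, motif_id, tissue, strand, region_id
    region_labels: dict[str, dict[str, int]]  # region_id -> tissue -> activity bit
    region_signal: dict[str, dict[str, float]]  # region_id -> tissue -> true mean signal

    def recompute_labels(self) -> dict[str, dict[str, int]]:
        """Re-derive activity bits from planted instances + activity_rule."""
        counts = {rid: {t: 0 for t in self.grammar.tissues} for rid in self.regions["region_id"]}
        for row in self.planted_instances.itertuples(index=False):
            if row.tissue == "open":  # accessibility-only motifs never confer activity
                continue
            targets = self.grammar.tissues if row.tissue == "shared" else [row.tissue]
            for t in targets:
                counts[row.region_id][t] += 1
        m = self.grammar.activity_rule
        return {rid: {t: int(c >= m) for t, c in tc.items()} for rid, tc in counts.items()}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "grammar": self.grammar.to_dict(),
            "regions": self.regions.to_dict(orient="list"),
            "planted_instances": self.planted_instances.to_dict(orient="list"),
            "region_labels": self.region_labels,
            "region_signal": self.region_signal,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            grammar=MotifGrammar.from_dict(payload["grammar"]),
            regions=pd.DataFrame(payload["regions"]),
            planted_instances=pd.DataFrame(payload["planted_instances"]),
            region_labels=payload["region_labels"],
            region_signal=payload["region_signal"],
        )


def generate_genome(n_chroms: int, chrom_length: int, seed: int) -> Genome:
    """Uniform-random ACGT genome; the last chromosome is flagged as holdout."""
    if n_chroms < 2:
        raise ValueError("need >= 2 chromosomes (one is reserved as the holdout test set)")
    if chrom_length < 50_000:
        raise ValueError("chrom_length must be >= 50,000")
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": rng.integers(0, 4, size=chrom_length, dtype=np.uint8) for i in range(n_chroms)}
    return Genome(chroms=chroms, holdout_chrom=f"chr{n_chroms}")


def plant_regulatory_landscape(
    genome: Genome,
    grammar: MotifGrammar,
    n_regions_per_tissue: int,
    seed: int,
    n_shared_regions: int | None = None,
    n_open_regions: int | None = None,
    max_instances: int = 5,
    margin: int = 2000,
    spacing: int = 6000,
) -> tuple[Genome, GroundTruth]:
    """Plant motif-bearing regions into a copy of ``genome``.

    Regions are 1,001 bp, spread over all chromosomes (including the
    holdout) with ``spacing`` bp between consecutive slots — comfortably
    above the 1.5 kb fold-gap requirement and wide enough that inaccessible
    control bins can be sampled between regions.  Each tissue region
    carries k ~ U{0..max_instances} instances of that tissue's motifs on
    random strands; shared regions carry shared motifs that count toward
    every tissue.
    """
    rng = np.random.default_rng(seed)
    if n_shared_regions is None:
        n_shared_regions = n_regions_per_tissue // 2
    if n_open_regions is None:
        n_open_regions = (n_regions_per_tissue // 2) if grammar.accessibility_motifs else 0
    if spacing < MIN_GAP:
        raise ValueError(f"spacing must be >= {MIN_GAP}")

    pitch = REGION_LENGTH + spacing
    slots = []
    for chrom in genome.names:
        pos = margin
        while pos + REGION_LENGTH + margin <= genome.length(chrom):
            slots.append((chrom, pos))
            pos += pitch
    kinds = (
        [t for t in grammar.tissues for _ in range(n_regions_per_tissue)]
        + ["shared"] * n_shared_regions
        + ["open"] * n_open_regions
    )
    if len(kinds) > len(slots):
        raise CapacityError(f"genome holds {len(slots)} region slots, {len(kinds)} requested")

    slot_idx = rng.choice(len(slots), size=len(kinds), replace=False)
    order = rng.permutation(len(kinds))

    new_genome = Genome(chroms={c: arr.copy() for c, arr in genome.chroms.items()}, holdout_chrom=genome.holdout_chrom)
    motif_ids = grammar.all_motifs()
    by_owner: dict[str, list[str]] = {}
    for mid, (_, owner) in motif_ids.items():
        by_owner.setdefault(owner, []).append(mid)

    region_rows, instance_rows = [], []
    region_labels: dict[str, dict[str, int]] = {}
    region_signal: dict[str, dict[str, float]] = {}
    for j, (kind_i, slot_i) in enumerate(zip(order, slot_idx)):
        kind = kinds[kind_i]
        chrom, start = slots[slot_i]
        end = start + REGION_LENGTH
        rid = f"region_{j:05d}"
        k = int(rng.integers(0, max_instances + 1))
        # place k non-overlapping motif instances inside the region
        occupied: list[tuple[int, int]] = []
        for _ in range(k):
            mid = by_owner[kind][rng.integers(len(by_owner[kind]))]
            consensus = motif_ids[mid][0]
            w = len(consensus)
            for _attempt in range(100):
                off = int(rng.integers(0, REGION_LENGTH - w + 1))
                if all(off + w <= a or off >= b for a, b in occupied):
                    break
            else:  # pragma: no cover - essentially impossible at k <= 5
                continue
            occupied.append((off, off + w))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = consensus if strand == "+" else reverse_complement(consensus)
            new_genome.chroms[chrom][start + off : start + off + w] = seq_to_codes(planted)
            instance_rows.append((chrom, start + off, start + off + w, mid, motif_ids[mid][1], strand, rid))
        k_eff = len(occupied)
        if kind in ("shared", "open"):
            # both raise signal in every tissue; only shared motifs activate
            signal_counts = {t: k_eff for t in grammar.tissues}
            activity_counts = signal_counts if kind == "shared" else {t: 0 for t in grammar.tissues}
        else:
            signal_counts = {t: (k_eff if t == kind else 0) for t in grammar.tissues}
            activity_counts = signal_counts
        region_rows.append((rid, chrom, start, end, kind, k_eff))
        region_labels[rid] = {t: int(activity_counts[t] >= grammar.activity_rule) for t in grammar.tissues}
        region_signal[rid] = {t: grammar.baseline + grammar.signal_gain * signal_counts[t] for t in grammar.tissues}

    regions = pd.DataFrame(region_rows, columns=["region_id", "chrom", "start", "end", "kind", "n_planted"])
    regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    instances = pd.DataFrame(
        instance_rows, columns=["chrom", "start", "end", "motif_id", "tissue", "strand", "region_id"]
    )
    truth = GroundTruth(
        grammar=copy.deepcopy(grammar),
        regions=regions,
        planted_instances=instances,
        region_labels=region_labels,
        region_signal=region_signal,
    )
    return new_genome, truth


def emit_fixtures(genome: Genome, truth: GroundTruth, out_dir: str | os.PathLike, seed: int = 0) -> dict[str, str]:
    """Write the file set downstream stages consume.

    genome FASTA; per-tissue bedGraph of noisy signal (log-normal around the
    true region mean, baseline-level noise between regions); BED of peaks
    (regions whose true signal exceeds baseline in any tissue); VISTA-style
    activity TSV; ground-truth JSON.
    """
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(seed)
    g = truth.grammar
    paths = {"fasta": os.path.join(out, "genome.fa")}
    genome.to_fasta(paths["fasta"])

    regions = truth.regions
    for tissue in g.tissues:
        rows = []
        for chrom in genome.names:
            sub = regions[regions["chrom"] == chrom]
            cursor = 0
            for row in sub.itertuples(index=False):
                if row.start > cursor:
                    noise = float(g.baseline * np.exp(rng.normal(0.0, g.noise_sd)))
                    rows.append((chrom, cursor, row.start, noise))
                true = truth.region_signal[row.region_id][tissue]
                rows.append((chrom, row.start, row.end, float(true * np.exp(rng.normal(0.0, g.noise_sd)))))
                cursor = row.end
            if cursor < genome.length(chrom):
                noise = float(g.baseline * np.exp(rng.normal(0.0, g.noise_sd)))
                rows.append((chrom, cursor, genome.length(chrom), noise))
        track = SignalTrack.from_records(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))
        paths[f"bedgraph_{tissue}"] = os.path.join(out, f"{tissue}.bedGraph")
        track.write_bedgraph(paths[f"bedgraph_{tissue}"])

    is_peak = regions["region_id"].map(
        lambda rid: max(truth.region_signal[rid].values()) > g.baseline
    )
    peaks = regions[is_peak].sort_values(["chrom", "start"])
    paths["peaks_bed"] = os.path.join(out, "peaks.bed")
    with open(paths["peaks_bed"], "w") as fh:
        for row in peaks.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.region_id}\t0\t.\n")

    paths["vista_tsv"] = os.path.join(out, "vista.tsv")
    with open(paths["vista_tsv"], "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        fh.write("id\tchrom\tstart\tend\t" + "\t".join(g.tissues) + "\n")
        for row in regions.itertuples(index=False):
            bits = "\t".join(str(truth.region_labels[row.region_id][t]) for t in g.tissues)
            fh.write(f"{row.region_id}\t{row.chrom}\t{row.start}\t{row.end}\t{bits}\n")

    paths["truth_json"] = os.path.join(out, "truth.json")
    truth.to_json(paths["truth_json"])
    with open(os.path.join(out, "holdout.txt"), "w") as fh:
        fh.write((genome.holdout_chrom or "") + "\n")
    paths["holdout"] = os.path.join(out, "holdout.txt")
    return paths
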