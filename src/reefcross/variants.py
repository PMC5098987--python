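"""Three-criteria screen for putative multi-copy / intragenomic ITS-2 variants.

Marker genes such as ITS-2 occur in many copies per genome, so two OTUs can
be variants of one organism rather than two taxa.  A pair is flagged as a
putative multi-copy variant only when it meets all three criteria:

(i)   co-occurrence — both OTUs present in (nearly) every sample where
      either is present;
(ii)  proportionality — abundances track each other across samples at a
      (near-)fixed ratio, measured as a signed squared Pearson correlation
      on variance-normalized abundances;
(iii) similarity — high aligned percent identity of the representative
      sequences, with gap columns counted as differences.

Pairs that co-occur proportionally but are divergent in sequence are
reported as shared-niche candidates (divergent types with similar ecology)
rather than variants.  An alignment-free k-mer cosine similarity is reported
alongside the aligned identity; for variants separated by deletion blocks it
falls below the aligned value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align

from .community import shifted_log, size_factors_median_ratio
from .io import CountTable

__all__ = [
    "ScreenThresholds",
    "co_occurrence",
    "proportionality_r2",
    "identity_aligned",
    "identity_distance",
    "classify_pair",
    "screen_pairs",
]


@dataclass
class ScreenThresholds:
    """Cut-offs for the three criteria.

    The defaults are interpretive: presence means at least one read,
    co-occurrence in at least 90% of either-present samples, a signed R^2 of
    at least 0.9 (separating "strong" from "moderate" proportionality), and
    97% aligned identity (the conventional OTU clustering radius).
    """

    presence_min_count: int = 1
    co_occurrence_min_fraction: float = 0.9
    r2_min: float = 0.9
    identity_min_percent: float = 97.0

    def __post_init__(self) -> None:
        if self.presence_min_count < 0:
            raise ValueError("presence_min_count must be >= 0")
        if not (0.0 <= self.co_occurrence_min_fraction <= 1.0):
            raise ValueError("co_occurrence_min_fraction must be in [0, 1]")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ValueError("r2_min must be in [0, 1]")
        if not (0.0 <= self.identity_min_percent <= 100.0):
            raise ValueError("identity_min_percent must be in [0, 100]")


def co_occurrence(counts_a, counts_b, presence_min_count: int = 1):
    """Samples where both OTUs are present, and the fraction of
    either-present samples that they share."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length vectors")
    if len(a) == 0:
        raise ValueError("empty abundance vectors")
    pa = a >= presence_min_count
    pb = b >= presence_min_count
    both = int(np.sum(pa & pb))
    either = int(np.sum(pa | pb))
    frac = both / either if either > 0 else 0.0
    return both, frac


def proportionality_r2(values_a, values_b) -> float:
    """Signed squared Pearson correlation of two normalized abundance vectors.

    Returns ``sign(r) * r^2`` (anti-proportional pairs come out negative).
    Zero variance in either vector leaves the measure undefined (NaN), which
    downstream classification treats as criterion-not-met.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(a) != len(b):
        raise ValueError("need >= 3 paired samples")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.sign(r) * r * r)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


def identity_aligned(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global end-to-end alignment.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1.  Identity is
    the number of matched columns over the alignment length, so gap columns
    count as differences.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = sorted((seq_a.upper(), seq_b.upper()))  # symmetry under swap
    aln = _aligner().align(seq_a, seq_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return 100.0 * matches / len(a_row)


def _kmer_profile(seq: str, k: int) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def identity_distance(seq_a: str, seq_b: str, k: int = 5) -> float:
    """Alignment-free percent similarity: cosine of the k-mer count profiles.

    A geometric sequence-space measure reported alongside the aligned
    identity; sequences shorter than k are an error.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError(f"sequences must be at least {k} bp")
    pa = _kmer_profile(seq_a, k)
    pb = _kmer_profile(seq_b, k)
    shared = set(pa) & set(pb)
    dot = sum(pa[m] * pb[m] for m in shared)
    na = np.sqrt(sum(v * v for v in pa.values()))
    nb = np.sqrt(sum(v * v for v in pb.values()))
    return 100.0 * dot / (na * nb)


def classify_pair(
    co_occurrence_fraction: float,
    r2: float,
    identity_percent: float,
    thresholds: ScreenThresholds | None = None,
) -> tuple[set[str], str]:
    """Apply the all-three rule; returns (criteria met, verdict).

    ``putative_multicopy`` requires all three criteria.  Pairs meeting
    co-occurrence and proportionality but not similarity are
    ``shared_niche_candidate``; anything else is ``distinct``.  NaN measures
    count as not met.
    """
    t = thresholds or ScreenThresholds()
    met: set[str] = set()
    if co_occurrence_fraction == co_occurrence_fraction and \
            co_occurrence_fraction >= t.co_occurrence_min_fraction:
        met.add("co_occurrence")
    if r2 == r2 and r2 >= t.r2_min:
        met.add("proportionality")
    if identity_percent == identity_percent and \
            identity_percent >= t.identity_min_percent:
        met.add("similarity")
    if met >= {"co_occurrence", "proportionality", "similarity"}:
        verdict = "putative_multicopy"
    elif met >= {"co_occurrence", "proportionality"}:
        verdict = "shared_niche_candidate"
    else:
        verdict = "distinct"
    return met, verdict


def screen_pairs(
    counts: CountTable,
    sequences: dict[str, str],
    pairs: list[tuple[str, str]] | None = None,
    thresholds: ScreenThresholds | None = None,
    normalized: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the three-criteria screen over OTU pairs.

    ``pairs`` defaults to all pairs sharing a clade annotation (or all pairs
    when the table carries no annotation); in practice callers restrict the
    screen to the differentially abundant OTUs.  Proportionality is computed
    on the variance-normalized table (median-of-ratios size factors and
    shifted log), on all samples; co-occurrence uses raw counts.
    """
    t = thresholds or ScreenThresholds()
    if pairs is None:
        ann = counts.otu_annotation
        if ann:
            groups: dict[str, list[str]] = {}
            for o in counts.otu_ids:
                groups.setdefault(ann.get(o, ""), []).append(o)
            pairs = [
                p for members in groups.values() if len(members) > 1
                for p in combinations(members, 2)
            ]
        else:
            pairs = list(combinations(counts.otu_ids, 2))
    if normalized is None:
        sf = size_factors_median_ratio(counts)
        normalized = shifted_log(counts, sf)
    index = {o: i for i, o in enumerate(counts.otu_ids)}
    n_samples = len(counts.sample_ids)

    rows = []
    for a, b in pairs:
        ia, ib = index[a], index[b]
        raw_a, raw_b = counts.counts[ia], counts.counts[ib]
        both, frac = co_occurrence(raw_a, raw_b, t.presence_min_count)
        r2 = proportionality_r2(normalized[ia], normalized[ib])
        if a in sequences and b in sequences:
            ident = identity_aligned(sequences[a], sequences[b])
            dist = identity_distance(sequences[a], sequences[b])
        else:
            ident = dist = float("nan")
        met, verdict = classify_pair(frac, r2, ident, t)
        rows.append(
            {
                "otu_a": a,
                "otu_b": b,
                "n_samples": n_samples,
                "co_occurrence_count": both,
                "co_occurrence_fraction": frac,
                "proportionality_r2": r2,
                "identity_aligned_percent": ident,
                "identity_distance_percent": dist,
                "criteria_met": ",".join(sorted(met)),
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)
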