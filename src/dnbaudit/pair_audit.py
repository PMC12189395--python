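"""Insert-size estimation, read mapping and improper-pair classification.

The device-artifact evidence for a read pair combines three observables:

* does the forward read run through into the adapter (short insert)?
* do the mates overlap-merge into a single insert (proper pairing)?
* is the barcode sequence inside the read the target barcode?

plus, for long inserts, whether each mate maps to the target reference.
These are combined into the four-case classification:

1. improperly paired, short insert — adapter present, mates do not
   merge, non-target barcode in the forward read;
2. properly paired but misdemultiplexed, short insert — adapter present,
   mates fully merge, non-target barcode in both reads;
3. improperly paired, long insert — no adapter, mates do not merge,
   forward unmapped to the target while the reverse maps;
4. excluded — long insert, mates consistent with a single non-target
   source; indistinguishable from physical cross-contamination, so the
   class is labelled but never counted as a device artifact.

The overlap merger and the k-mer seeded mapper are deliberately minimal
in-package equivalents of the usual external merge/map tools: only their
decisions (merged? mapped where?) feed the classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .demux_audit import extract_barcode
from .mgi_io import ReadPair, ReadRecord, revcomp
from .synthetic_run import ADAPTER_F, ADAPTER_R, BarcodePanel

__all__ = [
    "InsertEstimate",
    "MappingResult",
    "PairClass",
    "ReferenceIndex",
    "estimate_insert",
    "contains_adapter",
    "map_read",
    "classify_pair",
    "filter_short_inserts",
    "ca_group_stats",
]


@dataclass(frozen=True)
class InsertEstimate:
    """Mate-overlap merge outcome.

    For a standard innie overlap the insert is lenF + lenR − overlap; for
    read-through pairs (insert shorter than the read, mates engulfed) the
    insert equals the overlap-region length.
    """

    merged: bool
    overlap_length: int
    insert_length: Optional[int]
    mismatches_in_overlap: int


@lru_cache(maxsize=64)
def _shift_order(len_f: int, len_r: int, min_overlap: int) -> Tuple[int, ...]:
    """All innie shifts with overlap >= min_overlap, longest overlap first.

    Shift s places the reverse-complemented reverse read at offset s in
    forward-read coordinates; negative s is the read-through (engulfed)
    configuration."""
    return tuple(
        sorted(
            range(-(len_r - min_overlap), len_f - min_overlap + 1),
            key=lambda s: -(min(len_f, s + len_r) - max(0, s)),
        )
    )


def estimate_insert(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.25,
) -> InsertEstimate:
    """Scan all innie offsets of forward vs reverse-complemented reverse,
    pick the overlap with the lowest mismatch ratio (ties to the longest
    overlap), and merge if it satisfies the thresholds.

    Offsets are scanned in decreasing overlap order so a perfect overlap
    terminates the scan early.
    """
    fwd = pair.forward.sequence
    rcr = revcomp(pair.reverse.sequence)
    a = np.frombuffer(fwd.encode(), dtype=np.uint8)
    b = np.frombuffer(rcr.encode(), dtype=np.uint8)
    len_f, len_r = len(a), len(b)
    shifts = _shift_order(len_f, len_r, min_overlap)
    best: Optional[Tuple[float, int, int, int]] = None  # ratio, -overlap, s, mism
    for s in shifts:
        lo, hi = max(0, s), min(len_f, s + len_r)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        mism = int(np.count_nonzero(a[lo:hi] != b[lo - s:hi - s]))
        cand = (mism / overlap, -overlap, s, mism)
        if best is None or cand < best:
            best = cand
            if mism == 0:
                break  # no later (shorter) overlap can beat a perfect one
    if best is None:
        return InsertEstimate(False, 0, None, 0)
    ratio, neg_overlap, s, mism = best
    overlap = -neg_overlap
    merged = ratio <= max_mismatch_ratio
    insert = (s + len_r) if s >= 0 else (min(len_f, s + len_r) - 0)
    return InsertEstimate(
        merged=merged,
        overlap_length=overlap,
        insert_length=insert if merged else None,
        mismatches_in_overlap=mism,
    )


def contains_adapter(read: Union[ReadRecord, str], adapter_22mer: str = ADAPTER_F) -> bool:
    """Exact substring test for the partial adapter; a positive result
    marks a read-through (short-insert) read."""
    seq = read.sequence if isinstance(read, ReadRecord) else read
    return adapter_22mer in seq


@dataclass(frozen=True)
class MappingResult:
    """Outcome of the lightweight k-mer seeded mapping of one read."""

    mapped: bool
    reference_label: Optional[str] = None
    position: Optional[int] = None  # 0-based leftmost aligned base, forward strand
    strand: Optional[str] = None  # '+' or '-'
    identity: float = 0.0


class ReferenceIndex:
    """k-mer index over labelled reference sequences (forward strand);
    queries are tried on both strands of the read."""

    def __init__(self, references: Mapping[str, str], k: int = 15):
        if not references:
            raise ConfigError("no reference sequences supplied")
        self.k = k
        self.references = dict(references)
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for label, seq in self.references.items():
            if len(seq) < k:
                raise ConfigError(
                    f"reference {label!r} shorter than k={k} ({len(seq)} bases)"
                )
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos:pos + k], []).append((label, pos))

    def seed_hits(self, seq: str, n_seeds: int = 9) -> Dict[Tuple[str, int], int]:
        """Diagonal votes (label, read_start_on_ref) from sampled seeds."""
        k = self.k
        if len(seq) < k:
            return {}
        step = max(1, (len(seq) - k) // max(1, n_seeds - 1)) if len(seq) > k else 1
        votes: Dict[Tuple[str, int], int] = {}
        for off in range(0, len(seq) - k + 1, step):
            for label, pos in self._index.get(seq[off:off + k], ()):
                diag = (label, pos - off)
                votes[diag] = votes.get(diag, 0) + 1
        return votes


def _extend_diagonal(
    read_seq: str, ref_seq: str, diag: int
) -> Tuple[float, int, int]:
    """Best ungapped local segment along one diagonal (clipped at the
    reference ends): maximum-scoring run with match +1 / mismatch −2, so
    technical tails (adapter read-through, filler) are soft-clipped
    rather than sinking the identity of the genuine part.

    Returns (identity within the segment, segment length, leftmost
    reference position of the segment)."""
    lo_read = max(0, -diag)
    lo_ref = diag + lo_read
    span = min(len(read_seq) - lo_read, len(ref_seq) - lo_ref)
    if span <= 0:
        return 0.0, 0, 0
    a = np.frombuffer(read_seq[lo_read:lo_read + span].encode(), dtype=np.uint8)
    b = np.frombuffer(ref_seq[lo_ref:lo_ref + span].encode(), dtype=np.uint8)
    match = a == b
    score = np.where(match, 1.0, -2.0)
    cs = np.concatenate(([0.0], np.cumsum(score)))
    run_min = np.minimum.accumulate(cs[:-1])
    best_end = int(np.argmax(cs[1:] - run_min))  # segment ends at best_end (inclusive)
    if (cs[best_end + 1] - run_min[best_end]) <= 0:
        return 0.0, 0, 0
    start = int(np.argmin(cs[: best_end + 1]))
    seg = match[start:best_end + 1]
    return float(seg.mean()), int(seg.size), lo_ref + start


def map_read(
    read: Union[ReadRecord, str],
    index: ReferenceIndex,
    identity_min: float = 0.90,
    coverage_min: float = 0.50,
    max_diagonals: int = 5,
) -> MappingResult:
    """Seed-and-extend mapping: sample k-mer seeds, vote for (reference,
    diagonal) placements on both strands, extend the best diagonals
    ungapped, and call the read mapped if identity >= ``identity_min``
    over at least ``coverage_min`` of its length."""
    seq = read.sequence if isinstance(read, ReadRecord) else read
    best: Optional[Tuple[float, int, str, str, int]] = None
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        votes = index.seed_hits(query)
        top = sorted(votes.items(), key=lambda kv: -kv[1])[:max_diagonals]
        for (label, diag), _n in top:
            ident, aligned, ref_pos = _extend_diagonal(
                query, index.references[label], diag
            )
            if aligned < coverage_min * len(seq) or ident < identity_min:
                continue
            cand = (ident, aligned, label, strand, ref_pos)
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        return MappingResult(mapped=False)
    ident, _aligned, label, strand, ref_pos = best
    return MappingResult(
        mapped=True, reference_label=label, position=ref_pos,
        strand=strand, identity=ident,
    )


class PairClass(str, Enum):
    PROPER = "proper"
    CASE1_IMPROPER_PAIR_SHORT = "case1_improper_pair_short"
    CASE2_MISDEMUX_SHORT = "case2_misdemux_short"
    CASE3_IMPROPER_PAIR_LONG = "case3_improper_pair_long"
    CASE4_EXCLUDED = "case4_excluded"
    UNCLASSIFIED = "unclassified"


def _barcode_status(
    seq: str, adapter: str, panel: BarcodePanel, target_id: int
) -> str:
    """'target' / 'non_target' / 'unknown' from the in-read barcode.

    Only an exact match to a non-target whitelist barcode is evidence of
    misdemultiplexing; unextractable or off-whitelist 10-mers are not."""
    bc = extract_barcode(seq, adapter)
    if bc is None:
        return "unknown"
    bid = panel.sequence_to_id().get(bc)
    if bid is None:
        return "unknown"
    return "target" if bid == target_id else "non_target"


def classify_pair(
    pair: ReadPair,
    panel: BarcodePanel,
    target_id: int,
    index: Optional[ReferenceIndex] = None,
    target_reference_label: str = "target",
    adapter_f: str = ADAPTER_F,
    adapter_r: str = ADAPTER_R,
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.25,
) -> PairClass:
    """Assign one read pair to the four-case artifact scheme.

    The short/long split is the adapter-presence test on the forward read
    (presence bounds the insert at read_length − 22). Mapping evidence is
    consulted only for long-insert pairs; with no reference index those
    pairs stay PROPER (merged) or UNCLASSIFIED.
    """
    short = contains_adapter(pair.forward, adapter_f)
    est = estimate_insert(pair, min_overlap=min_overlap, max_mismatch_ratio=max_mismatch_ratio)

    if short:
        fwd_status = _barcode_status(pair.forward.sequence, adapter_f, panel, target_id)
        rev_status = _barcode_status(pair.reverse.sequence, adapter_r, panel, target_id)
        if not est.merged and fwd_status == "non_target":
            return PairClass.CASE1_IMPROPER_PAIR_SHORT
        if est.merged and fwd_status == "non_target" and rev_status == "non_target":
            return PairClass.CASE2_MISDEMUX_SHORT
        if est.merged and fwd_status != "non_target":
            return PairClass.PROPER
        return PairClass.UNCLASSIFIED

    if index is None:
        return PairClass.PROPER if est.merged else PairClass.UNCLASSIFIED

    fwd_map = map_read(pair.forward, index)
    rev_map = map_read(pair.reverse, index)
    fwd_on_target = fwd_map.mapped and fwd_map.reference_label == target_reference_label
    rev_on_target = rev_map.mapped and rev_map.reference_label == target_reference_label

    if not est.merged:
        if not fwd_on_target and rev_map.mapped:
            return PairClass.CASE3_IMPROPER_PAIR_LONG
        if fwd_on_target and rev_on_target:
            return PairClass.PROPER
        return PairClass.UNCLASSIFIED

    # merged long pair: both mates carry one fragment
    if (
        fwd_map.mapped and rev_map.mapped
        and fwd_map.reference_label == rev_map.reference_label
        and fwd_map.reference_label != target_reference_label
    ):
        return PairClass.CASE4_EXCLUDED
    return PairClass.PROPER


def filter_short_inserts(
    pairs: Iterable[ReadPair], adapter_22mer: str = ADAPTER_F
) -> Tuple[List[ReadPair], int]:
    """Discard whole pairs whose forward read contains the adapter — the
    recommended preprocessing step that removes the reads in which device
    artifacts are observable. Order-preserving and idempotent."""
    kept: List[ReadPair] = []
    removed = 0
    for pair in pairs:
        if contains_adapter(pair.forward, adapter_22mer):
            removed += 1
        else:
            kept.append(pair)
    return kept, removed


def ca_group_stats(
    pairs: Sequence[ReadPair],
    index: ReferenceIndex,
    target_reference_label: str = "target",
    contaminant_reference_label: Optional[str] = None,
    adapter_22mer: str = ADAPTER_F,
) -> pd.DataFrame:
    """Per-group forward-read mapping percentages, CA group vs total.

    CA ("contain adapter") pairs have inserts short enough that the
    forward read runs into the adapter. Columns: group, n, pct_unmapped
    (not mapped to the target reference) and pct_contaminant (mapped to
    the named contaminant reference; NaN when none is given)."""
    records = []
    maps = [map_read(p.forward, index) for p in pairs]
    ca_mask = [contains_adapter(p.forward, adapter_22mer) for p in pairs]
    for group, selector in (("CA", ca_mask), ("total", [True] * len(pairs))):
        selected = [m for m, keep in zip(maps, selector) if keep]
        n = len(selected)
        if n == 0:
            records.append({"group": group, "n": 0,
                            "pct_unmapped": float("nan"),
                            "pct_contaminant": float("nan")})
            continue
        unmapped = sum(
            1 for m in selected
            if not (m.mapped and m.reference_label == target_reference_label)
        )
        row = {"group": group, "n": n, "pct_unmapped": 100.0 * unmapped / n}
        if contaminant_reference_label is None:
            row["pct_contaminant"] = float("nan")
        else:
            contam = sum(
                1 for m in selected
                if m.mapped and m.reference_label == contaminant_reference_label
            )
            row["pct_contaminant"] = 100.0 * contam / n
        records.append(row)
    return pd.DataFrame.from_records(records)
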