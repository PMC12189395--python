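"""Truth-labelled synthetic DNBSEQ-style paired-end runs.

The generator emulates the features of DNBSEQ data that the audit stages
key on, and nothing else:

* MGI-style read names with a ``CxxRxx`` FOV token and a sequential
  ordinal identifier (neighbouring nanoballs get neighbouring ordinals);
* short-insert read-through: when the insert ``l`` is shorter than the
  read, the forward read continues into the partial left adapter
  (``CCAAGCGGTCTTAGGAAGACAA``) followed by the 10-base sample barcode,
  and the reverse read likewise into its own adapter
  (``CGTTCTGTGAGCCAAGGAGTTG``) and barcode;
* planted artifact classes with per-pair truth labels — misdemultiplexed
  pairs (wrong barcode inside the read), improper pairs (forward and
  reverse from different source fragments), optical duplicates at
  configurable ordinal offsets within the same FOV, and chimeric reads
  carrying two different inserts.

Artifact classes are mutually exclusive per pair; every stochastic choice
draws from a single seeded RNG stream in a fixed, documented order, so a
given config is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mgi_io import MgiReadName, ReadPair, ReadRecord, revcomp

__all__ = [
    "ADAPTER_F",
    "ADAPTER_R",
    "BarcodePanel",
    "InsertModel",
    "RunConfig",
    "simulate_pairs",
    "resolve_inputs",
    "generate_run",
    "truth_rates",
    "DEFAULT_OFFSET_WEIGHTS",
]

# Partial MGI adapter sequences that sit immediately left of the barcode
# in read-through reads (forward / reverse read respectively).
ADAPTER_F = "CCAAGCGGTCTTAGGAAGACAA"
ADAPTER_R = "CGTTCTGTGAGCCAAGGAGTTG"

BARCODE_LENGTH = 10

# Ordinal-offset modes of optical duplicates: one dominant nearest-neighbour
# mode plus four reproducible farther-neighbourhood modes.
DEFAULT_OFFSET_WEIGHTS: Dict[int, float] = {1: 0.80, 63: 0.05, 85: 0.05, 195: 0.05, 217: 0.05}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


def _add_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitutions at the given rate; substituted base always differs."""
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    k = int(mask.sum())
    if k == 0:
        return seq
    orig = _BASE_INDEX[arr[mask]]
    arr[mask] = _BASES[(orig + 1 + rng.integers(0, 3, k)) % 4]
    return bytes(arr).decode()


@dataclass(frozen=True)
class BarcodePanel:
    """Whitelist of 10-base sample barcodes keyed by integer ID."""

    barcodes: Mapping[int, str]

    def __post_init__(self) -> None:
        seqs = list(self.barcodes.values())
        if not seqs:
            raise ConfigError("barcode panel is empty")
        for bc in seqs:
            if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
                raise ConfigError(f"barcode {bc!r} is not a 10-base ACGT sequence")
        if len(set(seqs)) != len(seqs):
            raise ConfigError("barcode sequences must be unique")

    def __contains__(self, barcode_id: int) -> bool:
        return barcode_id in self.barcodes

    def __getitem__(self, barcode_id: int) -> str:
        return self.barcodes[barcode_id]

    @property
    def ids(self) -> List[int]:
        return sorted(self.barcodes)

    def sequence_to_id(self) -> Dict[str, int]:
        return {seq: bid for bid, seq in self.barcodes.items()}

    @classmethod
    def random(cls, n: int, rng: np.random.Generator, first_id: int = 97) -> "BarcodePanel":
        """Draw n distinct random barcodes with IDs first_id..first_id+n-1
        (mimicking an MGI index subset such as 97-104)."""
        seqs: Dict[int, str] = {}
        seen = set()
        bid = first_id
        while len(seqs) < n:
            bc = _rand_bases(rng, BARCODE_LENGTH)
            if bc in seen:
                continue
            seen.add(bc)
            seqs[bid] = bc
            bid += 1
        return cls(seqs)

    @classmethod
    def from_tsv(cls, path) -> "BarcodePanel":
        df = pd.read_csv(path, sep="\t", header=None, names=["barcode_id", "sequence"])
        return cls(dict(zip(df["barcode_id"].astype(int), df["sequence"].astype(str))))

    def to_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            for bid in self.ids:
                fh.write(f"{bid}\t{self.barcodes[bid]}\n")


@dataclass(frozen=True)
class InsertModel:
    """Insert-length distribution: normal (truncated), uniform, or fixed.

    Defaults reflect a run whose libraries are shorter than the
    recommended 2x read length: mean 460 bp, sd 150 bp, truncated to
    [50, 2 x read_length]. That leaves roughly a tenth of inserts short
    enough for the barcode to be visible at PE300.
    """

    name: str = "normal"
    mean: float = 460.0
    sd: float = 150.0
    low: int = 50
    high: Optional[int] = None  # defaults to 2 * read_length

    def draw(self, rng: np.random.Generator, high: int) -> int:
        low = self.low
        if low < 1:
            raise ConfigError(f"insert model lower bound must be >= 1, got {low}")
        if self.name == "fixed":
            value = int(round(self.mean))
            if value < 1:
                raise ConfigError(f"fixed insert length must be >= 1, got {value}")
            return value
        if self.name == "uniform":
            return int(rng.integers(low, high + 1))
        if self.name == "normal":
            for _ in range(1000):
                value = int(round(rng.normal(self.mean, self.sd)))
                if low <= value <= high:
                    return value
            raise ConfigError(
                f"insert model normal({self.mean},{self.sd}) cannot produce "
                f"lengths in [{low},{high}]"
            )
        raise ConfigError(f"unknown insert model {self.name!r}")


@dataclass
class RunConfig:
    """Study conditions for one synthetic run.

    ``duplicate_artifact_bias`` weights artifact pairs when choosing the
    source of a planted optical duplicate (signal mix-ups and duplicates
    share a physical cause — close nanoball neighbourhood).
    ``improper_short_enrichment`` multiplies the improper-pair probability
    for barcode-visible short inserts.
    """

    n_pairs: int = 50_000
    read_length: int = 300
    insert_model: InsertModel = field(default_factory=InsertModel)
    barcode_panel: Optional[BarcodePanel] = None  # default: 8 random barcodes, IDs 97-104
    target_barcode_id: int = 104
    misdemux_rate: float = 0.05
    misdemux_reverse_fraction: float = 0.2  # share of misdemux pairs also wrong on the reverse
    improper_pair_rate: float = 0.02
    improper_short_enrichment: float = 1.0
    duplicate_rate: float = 0.02
    duplicate_offset_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSET_WEIGHTS)
    )
    duplicate_artifact_bias: float = 1.0
    chimera_rate: float = 0.001
    substitution_error_rate: float = 0.001
    references: Optional[Mapping[str, str]] = None  # label -> sequence
    target_reference_label: str = "target"
    n_fovs: int = 50
    run_token: str = "SYN01"
    adapter_pad_f: str = ""  # optional extra left-adapter bases ahead of the printed 22-mer
    adapter_pad_r: str = ""
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.read_length < BARCODE_LENGTH + len(ADAPTER_F):
            raise ConfigError("read_length too short to carry adapter + barcode")
        for attr in ("misdemux_rate", "improper_pair_rate", "duplicate_rate",
                     "chimera_rate", "misdemux_reverse_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{attr} must be in [0, 1], got {v}")
        if self.misdemux_rate + self.improper_pair_rate + self.chimera_rate + self.duplicate_rate > 1.0:
            raise ConfigError("artifact rates sum above 1; classes are mutually exclusive")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ConfigError("substitution_error_rate must be in [0, 1]")
        if self.n_fovs < 1:
            raise ConfigError("n_fovs must be >= 1")
        if any(off <= 0 for off in self.duplicate_offset_weights):
            raise ConfigError("duplicate offsets must be positive")
        if self.duplicate_rate > 0 and sum(self.duplicate_offset_weights.values()) <= 0:
            raise ConfigError("duplicate offset weights must have positive mass")

    @property
    def barcode_visible_threshold(self) -> int:
        """Largest insert for which the full barcode fits in the read."""
        return self.read_length - (len(self.adapter_pad_f) + len(ADAPTER_F) + BARCODE_LENGTH)


def _fov_sizes(n_pairs: int, n_fovs: int) -> List[int]:
    base, extra = divmod(n_pairs, n_fovs)
    return [base + (1 if i < extra else 0) for i in range(n_fovs)]


def _fov_key(index: int) -> Tuple[int, int]:
    # lay FOVs on a 10-column grid: C001..C010, rows increasing
    return (index % 10 + 1, index // 10 + 1)


def _sample_fragment(ref: str, length: int, rng: np.random.Generator) -> str:
    if length > len(ref):
        raise ConfigError(
            f"insert length {length} exceeds reference length {len(ref)}"
        )
    start = int(rng.integers(0, len(ref) - length + 1))
    return ref[start:start + length]


# A complex real source essentially never yields two same-FOV reads that are
# coincidentally >= 95% identical over their full length; a desk-scale
# reference would. Fragment endpoints within one FOV are therefore kept at
# least this far apart (reads from fragments offset by d align at identity
# ~ (L - d) / (L + d), so d >= 16 stays safely below the 95% call line).
_MIN_FRAGMENT_SEPARATION = 32


class _FovFragmentRegistry:
    """Per-FOV record of sampled fragment endpoints, bucketed for O(1)
    minimum-separation checks."""

    def __init__(self) -> None:
        self._bins: Dict[Tuple[str, int], List[int]] = {}

    def clear_at(self, label: str, pos: int) -> bool:
        b = pos // _MIN_FRAGMENT_SEPARATION
        for bb in (b - 1, b, b + 1):
            for other in self._bins.get((label, bb), ()):
                if abs(other - pos) < _MIN_FRAGMENT_SEPARATION:
                    return False
        return True

    def register(self, label: str, pos: int) -> None:
        self._bins.setdefault((label, pos // _MIN_FRAGMENT_SEPARATION), []).append(pos)


def _sample_fragment_separated(
    ref: str,
    label: str,
    length: int,
    rng: np.random.Generator,
    registry: _FovFragmentRegistry,
    max_attempts: int = 100,
) -> str:
    """Sample a fragment whose endpoints keep the minimum within-FOV
    separation; degrades to an unconstrained draw when the reference is
    too crowded to satisfy it."""
    if length > len(ref):
        raise ConfigError(
            f"insert length {length} exceeds reference length {len(ref)}"
        )
    start = 0
    for _ in range(max_attempts):
        start = int(rng.integers(0, len(ref) - length + 1))
        if registry.clear_at(label, start) and registry.clear_at(label, start + length):
            break
    registry.register(label, start)
    registry.register(label, start + length)
    return ref[start:start + length]


class _PairDraft:
    """Mutable per-pair state before records are materialised."""

    __slots__ = ("fwd", "rev", "insert", "source", "planted", "bc_f", "bc_r")

    def __init__(self, fwd, rev, insert, source, planted, bc_f, bc_r):
        self.fwd = fwd
        self.rev = rev
        self.insert = insert
        self.source = source
        self.planted = planted
        self.bc_f = bc_f
        self.bc_r = bc_r


def _layout_read(core: str, adapter: str, barcode: str, read_length: int,
                 rng: np.random.Generator) -> str:
    """Assemble one read: insert, then adapter + barcode read-through, then
    random downstream technical filler, truncated to the read length."""
    s = core + adapter + barcode
    if len(s) < read_length:
        s += _rand_bases(rng, read_length - len(s))
    return s[:read_length]


def resolve_inputs(
    config: RunConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[BarcodePanel, Dict[str, str]]:
    """The barcode panel and references a config resolves to.

    Defaulted inputs are drawn first from the run's RNG stream, so calling
    this with no ``rng`` reproduces exactly the panel and references that
    :func:`simulate_pairs` used for the same config — downstream audit
    stages need both.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = config.barcode_panel or BarcodePanel.random(8, rng)
    if config.target_barcode_id not in panel:
        raise ConfigError(f"target barcode {config.target_barcode_id} not in panel")
    refs = dict(config.references) if config.references else {
        "target": _rand_bases(rng, 250_000),
        "contaminant": _rand_bases(rng, 250_000),
    }
    if not refs:
        raise ConfigError("references must be non-empty")
    return panel, refs


def simulate_pairs(config: RunConfig) -> Tuple[List[ReadPair], pd.DataFrame]:
    """Generate all read pairs plus the per-pair truth table.

    RNG draw order (single stream seeded with ``config.seed``): defaulted
    barcode panel, then defaulted references; then per FOV: for each pair in
    ordinal order — insert length, class selector, class-specific draws
    (fragment starts, wrong-barcode choice, reverse-corruption coin,
    chimera partner), filler bases, substitution noise; then the FOV's
    duplicate count and per-duplicate source/offset draws.
    """
    rng = np.random.default_rng(config.seed)
    panel, refs = resolve_inputs(config, rng)
    target_label = config.target_reference_label
    if target_label not in refs:
        raise ConfigError(f"target reference label {target_label!r} missing from references")
    other_labels = [lab for lab in refs if lab != target_label]

    non_target_ids = [bid for bid in panel.ids if bid != config.target_barcode_id]
    if config.misdemux_rate > 0 and not non_target_ids:
        raise ConfigError("misdemux planting needs at least one non-target barcode")

    R = config.read_length
    high = config.insert_model.high if config.insert_model.high is not None else 2 * R
    adapter_f = config.adapter_pad_f + ADAPTER_F
    adapter_r = config.adapter_pad_r + ADAPTER_R
    target_bc = panel[config.target_barcode_id]
    short_thr = config.barcode_visible_threshold
    err = config.substitution_error_rate

    offsets = sorted(config.duplicate_offset_weights)
    if offsets:
        off_w = np.array([config.duplicate_offset_weights[o] for o in offsets], dtype=float)
        off_w = off_w / off_w.sum()

    pairs: List[ReadPair] = []
    truth_rows: List[dict] = []

    for fov_index, m in enumerate(_fov_sizes(config.n_pairs, config.n_fovs)):
        if m == 0:
            continue
        col, row = _fov_key(fov_index)
        if config.duplicate_rate > 0 and offsets and m > 1 and m <= min(offsets):
            raise ConfigError(
                f"smallest duplicate offset {min(offsets)} exceeds FOV size {m}"
            )
        registry = _FovFragmentRegistry()
        drafts: List[_PairDraft] = []
        for j in range(m):
            ell = config.insert_model.draw(rng, high)
            u = float(rng.random())
            p_mis = config.misdemux_rate
            p_imp = config.improper_pair_rate * (
                config.improper_short_enrichment if ell <= short_thr else 1.0
            )
            if u < p_mis:
                cls = "misdemux"
            elif u < p_mis + p_imp:
                cls = "improper_pair"
            elif u < p_mis + p_imp + config.chimera_rate:
                cls = "chimera"
            else:
                cls = "none"

            if cls == "none":
                frag = _sample_fragment_separated(refs[target_label], target_label, ell, rng, registry)
                fwd = _layout_read(frag, adapter_f, target_bc, R, rng)
                rev = _layout_read(revcomp(frag), adapter_r, target_bc, R, rng)
                draft = _PairDraft(fwd, rev, ell, target_label, "none",
                                   config.target_barcode_id, config.target_barcode_id)
            elif cls == "misdemux":
                frag = _sample_fragment_separated(refs[target_label], target_label, ell, rng, registry)
                wrong_id = non_target_ids[int(rng.integers(0, len(non_target_ids)))]
                rev_wrong = float(rng.random()) < config.misdemux_reverse_fraction
                bc_r_id = wrong_id if rev_wrong else config.target_barcode_id
                fwd = _layout_read(frag, adapter_f, panel[wrong_id], R, rng)
                rev = _layout_read(revcomp(frag), adapter_r, panel[bc_r_id], R, rng)
                draft = _PairDraft(fwd, rev, ell, target_label, "misdemux",
                                   wrong_id, bc_r_id)
            elif cls == "improper_pair":
                fwd_label = (other_labels[int(rng.integers(0, len(other_labels)))]
                             if other_labels else target_label)
                frag_f = _sample_fragment_separated(refs[fwd_label], fwd_label, ell, rng, registry)
                wrong_id = (non_target_ids[int(rng.integers(0, len(non_target_ids)))]
                            if non_target_ids else config.target_barcode_id)
                ell_r = config.insert_model.draw(rng, high)
                frag_r = _sample_fragment_separated(refs[target_label], target_label, ell_r, rng, registry)
                fwd = _layout_read(frag_f, adapter_f, panel[wrong_id], R, rng)
                rev = _layout_read(revcomp(frag_r), adapter_r, target_bc, R, rng)
                draft = _PairDraft(fwd, rev, ell, fwd_label, "improper_pair",
                                   wrong_id, config.target_barcode_id)
            else:  # chimera: one read carrying two different inserts
                other = (other_labels[int(rng.integers(0, len(other_labels)))]
                         if other_labels else target_label)
                half = max(1, ell // 2)
                frag_a = _sample_fragment_separated(refs[target_label], target_label, ell - half, rng, registry) if ell > half else ""
                frag_b = _sample_fragment_separated(refs[other], other, half, rng, registry)
                core = frag_a + frag_b
                fwd = _layout_read(core, adapter_f, target_bc, R, rng)
                rev = _layout_read(revcomp(core), adapter_r, target_bc, R, rng)
                draft = _PairDraft(fwd, rev, ell, f"{target_label}+{other}", "chimera",
                                   config.target_barcode_id, config.target_barcode_id)

            draft.fwd = _add_noise(draft.fwd, err, rng)
            draft.rev = _add_noise(draft.rev, err, rng)
            drafts.append(draft)

        # second pass: convert eligible pairs into optical duplicates of an
        # earlier same-FOV pair at a mode offset
        if config.duplicate_rate > 0 and offsets and m > 1:
            n_dup = int(rng.binomial(m, config.duplicate_rate))
            used_sources: set = set()
            converted: set = set()
            for _ in range(n_dup):
                for _attempt in range(100):
                    candidates = [
                        i for i in range(m)
                        if i not in converted and i not in used_sources
                    ]
                    if not candidates:
                        break
                    if config.duplicate_artifact_bias != 1.0:
                        w = np.array(
                            [config.duplicate_artifact_bias
                             if drafts[i].planted in ("misdemux", "improper_pair") else 1.0
                             for i in candidates], dtype=float)
                        src = int(rng.choice(candidates, p=w / w.sum()))
                    else:
                        src = candidates[int(rng.integers(0, len(candidates)))]
                    off = offsets[int(rng.choice(len(offsets), p=off_w))]
                    tgt = src + off
                    if (tgt < m and tgt not in converted and tgt not in used_sources
                            and drafts[tgt].planted == "none"):
                        s = drafts[src]
                        d = drafts[tgt]
                        d.fwd = _add_noise(s.fwd, err, rng)
                        d.rev = _add_noise(s.rev, err, rng)
                        d.insert = s.insert
                        d.source = s.source
                        d.planted = f"duplicate_of:{src + 1}"
                        d.bc_f = s.bc_f
                        d.bc_r = s.bc_r
                        converted.add(tgt)
                        used_sources.add(src)
                        break
                # unplaceable duplicates are silently dropped; truth_rates
                # reports the realized rate

        quality = "I" * R
        for j, d in enumerate(drafts):
            name = MgiReadName(
                run_token=config.run_token, lane=1, fov_col=col, fov_row=row,
                ordinal=j + 1,
            )
            pair = ReadPair(
                ReadRecord(name.with_mate(1), d.fwd, quality),
                ReadRecord(name.with_mate(2), d.rev, quality),
            )
            pairs.append(pair)
            truth_rows.append({
                "stem": name.stem,
                "lane": 1,
                "fov_col": col,
                "fov_row": row,
                "ordinal": j + 1,
                "true_insert_length": d.insert,
                "true_source_label": d.source,
                "planted_class": d.planted,
                "true_barcode_id": d.bc_f,
                "true_barcode_id_rev": d.bc_r,
            })

    truth = pd.DataFrame(truth_rows)
    return pairs, truth


def truth_rates(truth: pd.DataFrame) -> Dict[str, float]:
    """Realized fraction of each planted class (duplicate_of:* collapsed
    to 'duplicate'); classes are mutually exclusive so fractions sum to 1."""
    if len(truth) == 0:
        raise ConfigError("empty truth table")
    cls = truth["planted_class"].str.replace(r"duplicate_of:\d+", "duplicate", regex=True)
    counts = cls.value_counts()
    n = len(truth)
    return {
        name: float(counts.get(name, 0)) / n
        for name in ("none", "misdemux", "improper_pair", "duplicate", "chimera")
    }


def generate_run(
    config: RunConfig,
    out_dir,
    prefix: str = "run",
    gzipped: bool = False,
) -> Tuple[Path, Path, pd.DataFrame]:
    """Write a full synthetic run: R1/R2 FASTQ plus the truth table TSV.

    Returns the two FASTQ paths and the truth DataFrame (also written to
    ``<prefix>_truth.tsv``).
    """
    from .mgi_io import write_fastq_pairs

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fq.gz" if gzipped else ".fq"
    p1 = out_dir / f"{prefix}_R1{suffix}"
    p2 = out_dir / f"{prefix}_R2{suffix}"
    pairs, truth = simulate_pairs(config)
    write_fastq_pairs(pairs, p1, p2)
    truth.to_csv(out_dir / f"{prefix}_truth.tsv", sep="\t", index=False)
    return p1, p2, truth
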