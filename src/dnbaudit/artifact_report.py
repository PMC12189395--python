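"""Association statistics and per-run artifact reporting.

The central question is whether artifact pairs (improperly paired or
misdemultiplexed) are enriched for close DNA-nanoball neighbourhood —
i.e. whether their reverse reads have nearby duplicates or nearby
same-sample neighbours — compared with the read pool as a whole. The
comparison is a 2x2 contingency: Pearson chi-square (1 df, no continuity
correction) for significance, and two effect sizes:

* ``rate_ratio`` — the ratio of the two proportions (the effect size
  matching the published per-proportion figures);
* ``odds_ratio`` — the textbook cross-product odds ratio.

Both are always reported, labelled unambiguously.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .errors import ConfigError, InputError
from .duplicate_scan import DEFAULT_FAST_OFFSETS, DuplicateHit
from .mgi_io import ReadPair

__all__ = [
    "Association2x2",
    "chi2_2x2",
    "rate_ratio",
    "odds_ratio",
    "neighbor_association",
    "RunReport",
    "build_report",
    "format_p_value",
]


def chi2_2x2(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2
    count table; p from the upper tail. Zero margins are an error."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise InputError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise InputError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InputError("all margins of the 2x2 table must be positive")
    statistic, p, _dof, _exp = stats.chi2_contingency(arr, correction=False)
    return float(statistic), float(p)


def rate_ratio(k1: int, n1: int, k2: int, n2: int) -> float:
    """Ratio of proportions (k1/n1) / (k2/n2); infinite when k2 == 0."""
    if n1 <= 0 or n2 <= 0:
        raise InputError("group sizes must be positive")
    if k2 == 0:
        return math.inf
    return (k1 / n1) / (k2 / n2)


def odds_ratio(k1: int, n1: int, k2: int, n2: int) -> float:
    """Cross-product odds ratio k1(n2-k2) / ((n1-k1)k2)."""
    if n1 <= 0 or n2 <= 0:
        raise InputError("group sizes must be positive")
    denom = (n1 - k1) * k2
    if denom == 0:
        return math.inf
    return (k1 * (n2 - k2)) / denom


def format_p_value(p: float) -> str:
    """Sub-representable p-values render as '< 1e-300'."""
    if p == 0.0 or p < 1e-300:
        return "< 1e-300"
    return f"{p:.3g}"


@dataclass(frozen=True)
class Association2x2:
    """Selected-vs-baseline neighbourhood association."""

    k_selected: int
    n_selected: int
    k_baseline: int
    n_baseline: int
    chi2_statistic: float
    p_value: float
    rate_ratio: float
    odds_ratio: float

    @property
    def selected_percent(self) -> float:
        return 100.0 * self.k_selected / self.n_selected

    @property
    def baseline_percent(self) -> float:
        return 100.0 * self.k_baseline / self.n_baseline

    def to_dict(self) -> Dict:
        return {
            "k_selected": self.k_selected,
            "n_selected": self.n_selected,
            "k_baseline": self.k_baseline,
            "n_baseline": self.n_baseline,
            "selected_percent": self.selected_percent,
            "baseline_percent": self.baseline_percent,
            "chi2_statistic": self.chi2_statistic,
            "p_value": self.p_value,
            "p_value_display": format_p_value(self.p_value),
            "rate_ratio": self.rate_ratio,
            "odds_ratio": self.odds_ratio,
        }


def _association_from_counts(
    k_sel: int, n_sel: int, k_base: int, n_base: int
) -> Association2x2:
    chi2_stat, p = chi2_2x2([[k_sel, n_sel - k_sel], [k_base, n_base - k_base]])
    return Association2x2(
        k_selected=k_sel,
        n_selected=n_sel,
        k_baseline=k_base,
        n_baseline=n_base,
        chi2_statistic=chi2_stat,
        p_value=p,
        rate_ratio=rate_ratio(k_sel, n_sel, k_base, n_base),
        odds_ratio=odds_ratio(k_sel, n_sel, k_base, n_base),
    )


def neighbor_association(
    selected: Sequence[ReadPair],
    baseline: Sequence[ReadPair],
    mode: str = "case13",
    hits: Optional[Sequence[DuplicateHit]] = None,
    offsets: Sequence[int] = DEFAULT_FAST_OFFSETS,
) -> Association2x2:
    """Test whether selected pairs' reverse reads are enriched for close
    nanoball neighbourhood relative to the baseline pool.

    mode='case13': the indicator is "the reverse read appears in a
    duplicate hit" (``hits`` must come from a scan over the same pool's
    reverse reads). mode='case2': the indicator is "some read of the
    same demultiplexed pool sits in the same FOV at an ordinal offset
    from the given set".

    The baseline is the full pool, so selecting the whole pool gives a
    rate ratio of exactly 1.
    """
    if len(selected) == 0:
        raise InputError("selected set is empty")
    if len(baseline) == 0:
        raise InputError("baseline pool is empty")

    if mode == "case13":
        if hits is None:
            raise ConfigError("mode 'case13' requires duplicate hits")
        flagged: Set[Tuple[Tuple[int, int, int], int]] = set()
        for h in hits:
            flagged.add((h.fov_key, h.ordinal_a))
            flagged.add((h.fov_key, h.ordinal_b))

        def indicator(pair: ReadPair) -> bool:
            name = pair.reverse.name
            return (name.fov_key, name.ordinal) in flagged

    elif mode == "case2":
        pool_ordinals: Dict[Tuple[int, int, int], Set[int]] = {}
        for pair in baseline:
            name = pair.reverse.name
            pool_ordinals.setdefault(name.fov_key, set()).add(name.ordinal)
        offsets = sorted(set(offsets))

        def indicator(pair: ReadPair) -> bool:
            name = pair.reverse.name
            fov = pool_ordinals.get(name.fov_key, ())
            return any(
                name.ordinal + off in fov or name.ordinal - off in fov
                for off in offsets
            )

    else:
        raise ConfigError(f"unknown association mode {mode!r}")

    k_sel = sum(1 for p in selected if indicator(p))
    k_base = sum(1 for p in baseline if indicator(p))
    return _association_from_counts(k_sel, len(selected), k_base, len(baseline))


@dataclass
class RunReport:
    """Consolidated per-run artifact report; absent stages stay None."""

    misdemux_forward: Optional[Dict] = None
    misdemux_reverse: Optional[Dict] = None
    scan: Optional[Dict] = None
    pair_classes: Optional[Dict[str, int]] = None
    associations: Optional[Dict[str, Dict]] = None
    filter_summary: Optional[Dict] = None

    def to_dict(self) -> Dict:
        return {
            "misdemux_forward": self.misdemux_forward,
            "misdemux_reverse": self.misdemux_reverse,
            "scan": self.scan,
            "pair_classes": self.pair_classes,
            "associations": self.associations,
            "filter_summary": self.filter_summary,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    def render_text(self) -> str:
        """Human-readable summary mirroring the count-table layouts of the
        audit stages."""
        lines: List[str] = ["DNBSEQ artifact audit report", "=" * 29]
        for label, section in (
            ("Forward-read misdemultiplexing", self.misdemux_forward),
            ("Reverse-read misdemultiplexing", self.misdemux_reverse),
        ):
            lines.append(f"\n{label}:")
            if section is None:
                lines.append("  (not run)")
                continue
            rate = section.get("rate")
            lines.append(
                f"  whitelist-matching barcodes: {section.get('n_exact_panel_match')}"
                f"  non-target: {section.get('n_non_target')}"
                f"  rate: {'NA' if rate is None else f'{100 * rate:.2f}%'}"
            )
            for item in section.get("contaminants", [])[:10]:
                lines.append(f"    {item['count']:>8}  barcode {item['barcode_id']}")
        lines.append("\nOptical duplicates:")
        if self.scan is None:
            lines.append("  (not run)")
        else:
            lines.append(
                f"  method: {self.scan.get('method')}  "
                f"reads with duplicates: {self.scan.get('n_reads_with_duplicate')}"
                f" / {self.scan.get('n_reads_processed')}"
                f"  rate: {100 * self.scan.get('rate', 0.0):.2f}%"
            )
        lines.append("\nPair classification:")
        if self.pair_classes is None:
            lines.append("  (not run)")
        else:
            for name, count in sorted(self.pair_classes.items()):
                lines.append(f"  {name:<28} {count}")
        lines.append("\nAssociations:")
        if self.associations is None:
            lines.append("  (not run)")
        else:
            for name, assoc in self.associations.items():
                lines.append(
                    f"  {name}: {assoc['selected_percent']:.2f}% vs "
                    f"{assoc['baseline_percent']:.3g}% "
                    f"(rate ratio {assoc['rate_ratio']:.2f}, "
                    f"odds ratio {assoc['odds_ratio']:.2f}, "
                    f"p {assoc['p_value_display']})"
                )
        lines.append("\nShort-insert filter:")
        if self.filter_summary is None:
            lines.append("  (not run)")
        else:
            lines.append(
                f"  kept {self.filter_summary.get('kept')} pairs, removed "
                f"{self.filter_summary.get('removed')}"
            )
        return "\n".join(lines)


def build_report(
    misdemux_forward=None,
    misdemux_reverse=None,
    scan=None,
    pair_classes: Optional[Dict[str, int]] = None,
    associations: Optional[Dict[str, "Association2x2"]] = None,
    filter_summary: Optional[Dict] = None,
) -> RunReport:
    """Assemble stage outputs (dataclasses or dicts) into one RunReport."""

    def _dictify(obj):
        if obj is None or isinstance(obj, dict):
            return obj
        return obj.to_dict()

    return RunReport(
        misdemux_forward=_dictify(misdemux_forward),
        misdemux_reverse=_dictify(misdemux_reverse),
        scan=_dictify(scan),
        pair_classes=dict(pair_classes) if pair_classes is not None else None,
        associations=(
            {name: _dictify(a) for name, a in associations.items()}
            if associations is not None
            else None
        ),
        filter_summary=filter_summary,
    )
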