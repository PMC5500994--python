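"""Multi-date tree matching and pruning-impact statistics.

Trees are matched across dates on their plantation (row, column) identity.
For a matched pair and each feature (projected area, height, volume) the
signed percent change is

    % = 100 * (feature_later - feature_earlier) / feature_earlier

Three standard comparisons are produced: *impact* (after vs before pruning),
*annual growth* (one year after vs after pruning) and *restoration* (one year
after vs before pruning).  Per-treatment summaries report the mean and sample
SD (divide by N-1) of the per-tree deltas and the mean of the per-tree
percentages; the ratio-of-means percentage is also computed since the two
aggregations differ on skewed data.  Pruning severity classes (<10%, 10-30%,
30-50%, >50% of crown volume removed) stratify annual volume growth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tree_metrics import TreeRecord

__all__ = [
    "MatchedPair",
    "MatchResult",
    "ChangeRecord",
    "TreatmentSummary",
    "SeverityClassSummary",
    "SEVERITY_CLASSES",
    "severity_class",
    "match_trees",
    "percent_change",
    "change_records",
    "summarize_change",
    "severity_class_growth",
    "coefficient_of_variation",
    "export_level_maps",
    "compare_dates",
]

FEATURES = ("area_m2", "height_m", "volume_m3")

#: Half-open severity classes (percent of crown volume removed), left-closed.
SEVERITY_CLASSES: tuple[tuple[float, float, str], ...] = (
    (0.0, 10.0, "<10%"),
    (10.0, 30.0, "10-30%"),
    (30.0, 50.0, "30-50%"),
    (50.0, math.inf, ">50%"),
)


def severity_class(severity_pct: float) -> str:
    s = max(0.0, float(severity_pct))
    for lo, hi, label in SEVERITY_CLASSES:
        if lo <= s < hi:
            return label
    return SEVERITY_CLASSES[-1][2]


@dataclass
class MatchedPair:
    key: tuple[int, int]  # (row, column)
    earlier: TreeRecord
    later: TreeRecord


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    unmatched_earlier: list[TreeRecord]
    unmatched_later: list[TreeRecord]
    excluded_unreliable: list[tuple[int, int]]


def match_trees(records_a: Sequence[TreeRecord], records_b: Sequence[TreeRecord]
                ) -> MatchResult:
    """Pair trees across two dates on (row, column).

    Only pairs where both records are reliable enter downstream statistics;
    unreliable or unmatched trees are reported for QC.  Duplicate (row,
    column) keys within one date raise an error.
    """
    def index(records, label):
        out: dict[tuple[int, int], TreeRecord] = {}
        for rec in records:
            key = (rec.row, rec.column)
            if key in out:
                raise ValueError(f"duplicate grid key {key} in {label} records")
            out[key] = rec
        return out

    a = index(records_a, "earlier")
    b = index(records_b, "later")
    pairs: list[MatchedPair] = []
    excluded: list[tuple[int, int]] = []
    for key in sorted(set(a) & set(b)):
        if a[key].reliable and b[key].reliable:
            pairs.append(MatchedPair(key=key, earlier=a[key], later=b[key]))
        else:
            excluded.append(key)
    return MatchResult(
        pairs=pairs,
        unmatched_earlier=[a[k] for k in sorted(set(a) - set(b))],
        unmatched_later=[b[k] for k in sorted(set(b) - set(a))],
        excluded_unreliable=excluded,
    )


def percent_change(value_later: float, value_earlier: float) -> float:
    """Signed percent change, 100 * (later - earlier) / earlier.

    Raises ``ValueError`` on a non-positive baseline (the caller excludes and
    logs such trees).
    """
    if not value_earlier > 0:
        raise ValueError(f"baseline must be positive, got {value_earlier}")
    return 100.0 * (value_later - value_earlier) / value_earlier


@dataclass
class ChangeRecord:
    """Per-tree feature deltas and percent changes for one date pair."""

    tree_id: int
    row: int
    column: int
    treatment: str
    delta: dict[str, float]
    percent: dict[str, float]


def change_records(pairs: Iterable[MatchedPair]) -> list[ChangeRecord]:
    """Per-tree deltas/percentages; trees with a non-positive baseline are
    excluded (with a warning)."""
    out: list[ChangeRecord] = []
    skipped = 0
    for pair in pairs:
        deltas: dict[str, float] = {}
        percents: dict[str, float] = {}
        ok = True
        for feat in FEATURES:
            earlier = getattr(pair.earlier, feat)
            later = getattr(pair.later, feat)
            deltas[feat] = later - earlier
            try:
                percents[feat] = percent_change(later, earlier)
            except ValueError:
                ok = False
                break
        if not ok:
            skipped += 1
            continue
        out.append(ChangeRecord(
            tree_id=pair.later.tree_id, row=pair.key[0], column=pair.key[1],
            treatment=pair.later.treatment or pair.earlier.treatment,
            delta=deltas, percent=percents))
    if skipped:
        warnings.warn(f"{skipped} tree(s) excluded: non-positive baseline feature",
                      stacklevel=2)
    return out


@dataclass
class TreatmentSummary:
    """Per-treatment mean +/- SD of deltas and mean percent change."""

    treatment: str
    comparison: str
    n_trees: int
    mean: dict[str, float]
    sd: dict[str, float]
    mean_percent: dict[str, float]         # mean of per-tree ratios (headline)
    percent_of_means: dict[str, float]     # ratio-of-means alternative
    low_n: bool = False

    def to_row(self) -> dict:
        row: dict = {"treatment": self.treatment, "comparison": self.comparison,
                     "n_trees": self.n_trees}
        for feat in FEATURES:
            stem = feat.split("_")[0]
            row[f"{stem}_mean"] = self.mean[feat]
            row[f"{stem}_sd"] = self.sd[feat]
            row[f"{stem}_pct"] = self.mean_percent[feat]
            row[f"{stem}_pct_of_means"] = self.percent_of_means[feat]
        return row


def summarize_change(pairs: Sequence[MatchedPair], comparison: str = "",
                     ) -> list[TreatmentSummary]:
    """Treatment-level summaries of per-tree change for one date pair.

    Means/SDs are over the per-tree deltas (sample SD); the percent column is
    the mean of per-tree percent changes.  Empty groups are omitted with a
    warning; single-tree groups get SD 0 and a low-n flag.
    """
    records = change_records(pairs)
    pairs_by_key = {p.key: p for p in pairs}
    treatments = sorted({r.treatment for r in records})
    summaries: list[TreatmentSummary] = []
    for treatment in treatments:
        group = [r for r in records if r.treatment == treatment]
        if not group:
            warnings.warn(f"treatment {treatment!r} has no matched trees",
                          stacklevel=2)
            continue
        mean, sd, mean_pct, pct_of_means = {}, {}, {}, {}
        for feat in FEATURES:
            deltas = np.array([r.delta[feat] for r in group])
            pcts = np.array([r.percent[feat] for r in group])
            base = float(sum(getattr(pairs_by_key[(r.row, r.column)].earlier, feat)
                             for r in group))
            mean[feat] = float(deltas.mean())
            sd[feat] = float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0
            mean_pct[feat] = float(pcts.mean())
            pct_of_means[feat] = (100.0 * float(deltas.sum()) / base
                                  if base > 0 else float("nan"))
        summaries.append(TreatmentSummary(
            treatment=treatment, comparison=comparison, n_trees=len(group),
            mean=mean, sd=sd, mean_percent=mean_pct,
            percent_of_means=pct_of_means, low_n=len(group) < 2))
    return summaries


@dataclass
class SeverityClassSummary:
    severity_class: str
    treatment: str
    n_trees: int
    mean_growth_pct: float
    sd_growth_pct: float


def severity_class_growth(pairs_12: Sequence[MatchedPair],
                          pairs_23: Sequence[MatchedPair]
                          ) -> list[SeverityClassSummary]:
    """Annual volume growth stratified by pruning severity and treatment.

    Severity is the percent of crown volume removed between the first two
    dates (negated percent change, clipped at 0); growth is the percent
    volume change over the following year.  Trees missing either date pair
    are excluded.
    """
    growth_by_key = {}
    for pair in pairs_23:
        try:
            growth_by_key[pair.key] = percent_change(
                pair.later.volume_m3, pair.earlier.volume_m3)
        except ValueError:
            continue
    rows = []
    for pair in pairs_12:
        if pair.key not in growth_by_key:
            continue
        try:
            impact = percent_change(pair.later.volume_m3, pair.earlier.volume_m3)
        except ValueError:
            continue
        severity = max(0.0, -impact)
        rows.append((severity_class(severity),
                     pair.later.treatment or pair.earlier.treatment,
                     growth_by_key[pair.key]))
    summaries: list[SeverityClassSummary] = []
    class_order = [label for _, _, label in SEVERITY_CLASSES]
    for label in class_order:
        for treatment in sorted({t for c, t, _ in rows if c == label}):
            growths = np.array([g for c, t, g in rows
                                if c == label and t == treatment])
            summaries.append(SeverityClassSummary(
                severity_class=label, treatment=treatment,
                n_trees=int(growths.size),
                mean_growth_pct=float(growths.mean()),
                sd_growth_pct=float(growths.std(ddof=1)) if growths.size > 1 else 0.0,
            ))
    return summaries


def coefficient_of_variation(records: Sequence[TreeRecord], feature: str) -> float:
    """CV in percent: 100 * sample SD / mean of a feature over the records."""
    if not records:
        raise ValueError("empty record set")
    vals = np.array([getattr(r, feature) for r in records], dtype=float)
    mean = vals.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return float(100.0 * sd / mean)


def export_level_maps(records: Sequence[TreeRecord], feature: str,
                      path: str | Path, n_levels: int = 4,
                      values: Sequence[float] | None = None) -> None:
    """Write a GeoJSON map of per-tree polygons ranked into quantile levels.

    ``values`` overrides the ranked quantity (e.g. per-tree deltas between two
    dates); by default the named feature of each record is ranked.  Levels are
    1..n_levels by quantile; a constant feature puts every tree at level 1
    with a warning.
    """
    import json

    from .raster_model import _record_geometry, _record_properties

    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    records = list(records)
    if not records:
        raise ValueError("no records")
    if values is None:
        vals = np.array([getattr(r, feature) for r in records], dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        if vals.size != len(records):
            raise ValueError("values length must match records")
    if np.allclose(vals, vals[0]):
        warnings.warn("constant feature: all trees assigned level 1", stacklevel=2)
        levels = np.ones(vals.size, dtype=int)
    else:
        edges = np.quantile(vals, np.linspace(0, 1, n_levels + 1)[1:-1])
        levels = np.searchsorted(edges, vals, side="right") + 1
    features = []
    for rec, val, level in zip(records, vals, levels):
        props = _record_properties(rec)
        props["level"] = int(level)
        props["level_feature"] = feature
        props["level_value"] = round(float(val), 2)
        features.append({"type": "Feature", "geometry": _record_geometry(rec),
                         "properties": props})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


# ---------------------------------------------------------------------------
# Convenience: the three standard comparisons of the study
# ---------------------------------------------------------------------------

@dataclass
class ChangeAnalysis:
    impact: list[TreatmentSummary]       # date 2 vs date 1
    growth: list[TreatmentSummary]       # date 3 vs date 2
    restoration: list[TreatmentSummary]  # date 3 vs date 1
    severity: list[SeverityClassSummary]
    matches: dict[str, MatchResult]

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name, summaries in (("impact", self.impact), ("growth", self.growth),
                                ("restoration", self.restoration)):
            out[name] = pd.DataFrame([s.to_row() for s in summaries])
        out["severity_growth"] = pd.DataFrame(
            [{"severity_class": s.severity_class, "treatment": s.treatment,
              "n_trees": s.n_trees, "mean_growth_pct": s.mean_growth_pct,
              "sd_growth_pct": s.sd_growth_pct} for s in self.severity])
        return out


def compare_dates(records_1: Sequence[TreeRecord], records_2: Sequence[TreeRecord],
                  records_3: Sequence[TreeRecord]) -> ChangeAnalysis:
    """Run the full three-date analysis: impact, annual growth, restoration."""
    m12 = match_trees(records_1, records_2)
    m23 = match_trees(records_2, records_3)
    m13 = match_trees(records_1, records_3)
    return ChangeAnalysis(
        impact=summarize_change(m12.pairs, "date2-date1"),
        growth=summarize_change(m23.pairs, "date3-date2"),
        restoration=summarize_change(m13.pairs, "date3-date1"),
        severity=severity_class_growth(m12.pairs, m23.pairs),
        matches={"date1-date2": m12, "date2-date3": m23, "date1-date3": m13},
    )
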