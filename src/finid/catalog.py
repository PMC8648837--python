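"""Archive parsing and curation.

Handles the bookkeeping around a photo-identification archive: the
alphanumeric identity-label grammar (ecotype letter + documentation
number + birth-order suffixes, e.g. T109, T109A2), per-identity frequency
ranking over all vs. single-labeled images, head/long-tail selection,
the 5-second burst-series de-duplication rule, and deterministic
stratified train/validation/test splitting.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IdentityLabel", "CatalogRecord", "IntervalRule", "SplitSpec",
    "ParseResult", "parse_label", "parse_archive", "frequency_ranking",
    "select_head", "interval_filter", "make_splits", "write_manifest",
]

log = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"([A-Z])(\d+)([A-Z0-9]*)")


@dataclass(frozen=True)
class IdentityLabel:
    """One identity label: ecotype letter, number, generation suffix."""
    raw: str
    ecotype_prefix: str
    lineage_digits_and_suffix: str

    def __str__(self):
        return self.raw


def parse_label(raw: str) -> IdentityLabel:
    m = _LABEL_RE.fullmatch(raw.strip())
    if m is None:
        raise ValueError(f"label {raw!r} violates the label grammar")
    return IdentityLabel(raw=m.group(0), ecotype_prefix=m.group(1),
                         lineage_digits_and_suffix=m.group(2) + m.group(3))


@dataclass
class CatalogRecord:
    """One photograph with its identity labels and capture metadata."""
    image_path: Path
    labels: list
    photographer: str
    date: datetime.date | None
    time: datetime.time | None
    gps: tuple | None = None

    @property
    def single_labeled(self) -> bool:
        return len(self.labels) == 1

    @property
    def timestamp(self) -> datetime.datetime | None:
        if self.date is None or self.time is None:
            return None
        return datetime.datetime.combine(self.date, self.time)

    @property
    def label_set(self) -> set:
        return {str(l) for l in self.labels}


@dataclass(frozen=True)
class IntervalRule:
    """Keep only the first frame of a burst series.

    Frames shot by the same photographer on the same date chain into a
    series while consecutive gaps stay within ``delta`` seconds
    (``chained=True``), or while the gap to the series' first frame does
    (``chained=False``).
    """
    delta: float = 5.0
    chained: bool = True

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class SplitSpec:
    ratios: tuple = (0.75, 0.13, 0.12)
    interval_rule_applies_to: frozenset = frozenset({"val", "test"})
    rule: IntervalRule = field(default_factory=IntervalRule)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9 or len(self.ratios) != 3:
            raise ValueError("ratios must be three fractions summing to 1")


@dataclass
class ParseResult:
    records: list
    rejects: pd.DataFrame    # columns: image_path, reason

    def write_rejects(self, path):
        self.rejects.to_csv(path, index=False)


def parse_archive(root, require_labels: bool = True) -> ParseResult:
    """Read an archive's metadata.csv into validated CatalogRecords.

    Malformed rows (missing file, bad label grammar, unparseable
    timestamp, empty label list) are routed to the rejects report with a
    reason instead of being silently dropped.
    """
    root = Path(root)
    meta = root / "metadata.csv"
    if not meta.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {meta}")
    df = pd.read_csv(meta, dtype=str, keep_default_na=False)
    records, rejects = [], []
    for row in df.itertuples(index=False):
        path = root / row.image_path
        try:
            if not path.exists():
                raise ValueError("image file missing")
            raw_labels = [s for s in str(row.labels).split(";") if s.strip()]
            if not raw_labels and require_labels:
                raise ValueError("no labels")
            labels = [parse_label(s) for s in raw_labels]
            date = (datetime.date.fromisoformat(row.date)
                    if row.date else None)
            time = (datetime.time.fromisoformat(row.time)
                    if row.time else None)
            gps = None
            if row.lat and row.lon:
                gps = (float(row.lat), float(row.lon))
            records.append(CatalogRecord(image_path=path, labels=labels,
                                         photographer=row.photographer,
                                         date=date, time=time, gps=gps))
        except ValueError as exc:
            reason = str(exc)
            if "grammar" in reason:
                reason = "label grammar"
            rejects.append({"image_path": row.image_path, "reason": reason})
    return ParseResult(records=records,
                       rejects=pd.DataFrame(rejects,
                                            columns=["image_path", "reason"]))


def frequency_ranking(records, by: str = "count_single") -> pd.DataFrame:
    """Images per identity, over all images and over single-labeled ones.

    Returns a DataFrame (identity, count_all, count_single) sorted by the
    requested count descending, ties broken lexicographically by label.
    """
    all_counts: dict[str, int] = {}
    single_counts: dict[str, int] = {}
    for rec in records:
        for lbl in rec.label_set:
            all_counts[lbl] = all_counts.get(lbl, 0) + 1
        if rec.single_labeled:
            lbl = str(rec.labels[0])
            single_counts[lbl] = single_counts.get(lbl, 0) + 1
    rows = [{"identity": k, "count_all": v,
             "count_single": single_counts.get(k, 0)}
            for k, v in all_counts.items()]
    df = pd.DataFrame(rows, columns=["identity", "count_all", "count_single"])
    if len(df):
        df = df.sort_values([by, "identity"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)
    return df


def select_head(ranked: pd.DataFrame, n: int):
    """Top-n identities by single-label count, plus head coverage.

    Coverage = single-labeled images of head identities / all
    single-labeled images (the head/long-tail boundary statistic).
    """
    if n > len(ranked):
        raise ValueError(f"n={n} exceeds {len(ranked)} identities")
    head = ranked.sort_values(["count_single", "identity"],
                              ascending=[False, True],
                              kind="stable").iloc[:n]
    total = ranked["count_single"].sum()
    coverage = float(head["count_single"].sum() / total) if total else 0.0
    return set(head["identity"]), coverage


def interval_filter(records, rule: IntervalRule = IntervalRule()):
    """Drop all but the first frame of each burst series.

    Grouping is by (date, photographer); within a group records are
    sorted by time (ties broken by file name), chained into series per
    the rule, and only series heads survive. Records without a
    timestamp pass through unfiltered (logged). Input order of the
    survivors is preserved.
    """
    keyed: dict = {}
    passthrough = []
    for idx, rec in enumerate(records):
        if rec.timestamp is None:
            log.warning("record %s has no timestamp; passed through",
                        rec.image_path)
            passthrough.append(idx)
            continue
        keyed.setdefault((rec.date, rec.photographer), []).append(idx)
    keep = set(passthrough)
    for group in keyed.values():
        group = sorted(group, key=lambda i: (records[i].timestamp,
                                             str(records[i].image_path)))
        series_head_t = None
        prev_t = None
        for i in group:
            t = records[i].timestamp
            ref = prev_t if rule.chained else series_head_t
            if ref is None or (t - ref).total_seconds() > rule.delta:
                keep.add(i)
                series_head_t = t
            prev_t = t
    return [rec for i, rec in enumerate(records) if i in keep]


def make_splits(records, spec: SplitSpec) -> dict:
    """Deterministic stratified train/val/test split.

    The partition is exhaustive and disjoint before de-duplication; the
    5-second interval rule is then applied only to the subsets named in
    ``spec.interval_rule_applies_to`` (training material is deliberately
    left untouched — augmentation de-correlates near-duplicates there).
    Stratification is per primary identity: every identity with at
    least 3 images contributes to all three splits.
    """
    rng = np.random.default_rng(spec.seed)
    groups: dict = {}
    for idx, rec in enumerate(records):
        key = str(rec.labels[0]) if rec.labels else ""
        groups.setdefault(key, []).append(idx)
    split_idx = {"train": [], "val": [], "test": []}
    r_train, r_val, r_test = spec.ratios
    for key in sorted(groups):
        idxs = np.array(groups[key])
        rng.shuffle(idxs)
        n = len(idxs)
        n_val = int(round(n * r_val))
        n_test = int(round(n * r_test))
        if n >= 3:
            n_val = max(n_val, 1)
            n_test = max(n_test, 1)
        n_train = n - n_val - n_test
        split_idx["train"].extend(idxs[:n_train])
        split_idx["val"].extend(idxs[n_train:n_train + n_val])
        split_idx["test"].extend(idxs[n_train + n_val:])
    out = {}
    for name, idxs in split_idx.items():
        subset = [records[i] for i in sorted(idxs)]
        if name in spec.interval_rule_applies_to:
            subset = interval_filter(subset, spec.rule)
        out[name] = subset
    return out


def write_manifest(records, path):
    """Write a split manifest: one image path per line."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(str(rec.image_path) + "\n")
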