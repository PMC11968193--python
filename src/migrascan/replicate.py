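"""Replicated-comparison inference: control-comparison exclusion, interval
merge/intersection across comparisons, gene-proximity annotation,
parallelism/convergence classification, XP-EHH directionality concordance
and the simplified functional categorization.

All intervals are 0-based half-open (BED semantics); a site is the
length-1 interval ``[pos - 1, pos)``.  Adjacent intervals sharing only a
boundary ([0,10) and [10,20)) do not overlap and do not merge, but their
bp distance is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def _as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval table lacks columns {missing}")
    out = df[INTERVAL_COLUMNS].drop_duplicates()
    if (out["end"] <= out["start"]).any():
        raise ValueError("intervals must satisfy start < end")
    return out.sort_values(INTERVAL_COLUMNS, kind="mergesort").reset_index(drop=True)


def sites_to_intervals(sites: pd.DataFrame) -> pd.DataFrame:
    """Length-1 intervals for 1-based site positions."""
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"].astype(int) - 1,
            "end": sites["pos"].astype(int),
        }
    )
    return _as_intervals(out)


def _overlaps_any(items: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each item overlap any interval in ``others``?"""
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in others.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    mask = np.zeros(len(items), dtype=bool)
    for i, row in enumerate(items.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(int(row.start), int(row.end)):
            mask[i] = True
    return mask


def exclude_control_outliers(
    case: pd.DataFrame, controls: list[pd.DataFrame]
) -> pd.DataFrame:
    """Remove every case item overlapping any control-comparison item.

    For site-level sets (length-1 intervals) overlap degenerates to exact
    position identity.  Output is always a subset of the input.
    """
    case = _as_intervals(case)
    nonempty = [_as_intervals(c) for c in controls if len(c)]
    if not nonempty:
        return case
    drop = np.zeros(len(case), dtype=bool)
    for ctrl in nonempty:
        drop |= _overlaps_any(case, ctrl)
    return case.loc[~drop].reset_index(drop=True)


def merge_overlapping(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping intervals per chromosome (half-open: intervals
    touching only at a boundary stay separate)."""
    iv = _as_intervals(intervals)
    rows = []
    for chrom, grp in iv.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict: [0,10) and [10,20) do not merge
                cur_e = max(cur_e, e)
            else:
                rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def intersect_across(sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assign each merged item of the union the comparisons overlapping it.

    Returns chrom/start/end plus one boolean column per comparison label
    and ``membership`` (comma-joined labels).  With three comparisons the
    membership patterns are the seven exclusive Venn regions.
    """
    if len(sets) < 2:
        raise ValueError("need at least two comparisons to intersect")
    labels = list(sets)
    union = merge_overlapping(pd.concat([_as_intervals(s) for s in sets.values()]))
    out = union.copy()
    for label in labels:
        out[label] = _overlaps_any(union, _as_intervals(sets[label]))
    out["membership"] = [
        ",".join(lab for lab in labels if row[lab]) for _, row in out.iterrows()
    ]
    return out


def genes_near(
    items: pd.DataFrame, annotation: pd.DataFrame, max_dist_bp: int = 25_000
) -> pd.DataFrame:
    """Item -> gene hits within ``max_dist_bp`` (inclusive; 0 = overlap).

    The bp distance between half-open intervals a and b is
    ``max(0, a.start - b.end, b.start - a.end)``, so abutting intervals
    are at distance 0 and a site exactly 25,000 bp past a gene edge is
    still a hit at the default threshold.
    """
    if annotation.empty:
        raise ValueError("gene annotation is empty")
    items = _as_intervals(items)
    known_chroms = set(annotation["chrom"])
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in annotation.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (max(int(s) - max_dist_bp, 0) - 1, int(e) + max_dist_bp + 1, (gid, int(s), int(e)))
            for gid, s, e in zip(grp["gene_id"], grp["start"], grp["end"])
        )
    rows = []
    missing_chroms = set()
    for row in items.itertuples(index=False):
        if row.chrom not in known_chroms:
            missing_chroms.add(row.chrom)
            continue
        for hit in trees[row.chrom].overlap(int(row.start), int(row.end)):
            gid, gs, ge = hit.data
            dist = max(0, int(row.start) - ge, gs - int(row.end))
            if dist <= max_dist_bp:
                rows.append(
                    {
                        "chrom": row.chrom,
                        "start": int(row.start),
                        "end": int(row.end),
                        "gene_id": gid,
                        "distance": dist,
                    }
                )
    if missing_chroms:
        logger.info("genes_near: no annotation for chromosomes %s", sorted(missing_chroms))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "distance"])


@dataclass
class ParallelismReport:
    """Membership and Venn summaries for one level (SNP or gene).

    ``membership``: item x comparison boolean frame (index = item key).
    ``region_counts``: exclusive Venn region -> count, keyed by the
    frozenset of comparison labels.
    """

    level: str
    membership: pd.DataFrame
    region_counts: dict[frozenset, int]
    union_size: int
    shared_two_plus: int
    shared_all: int

    def __post_init__(self) -> None:
        assert sum(self.region_counts.values()) == self.union_size
        assert self.shared_all <= self.shared_two_plus <= self.union_size

    def region_table(self) -> pd.DataFrame:
        rows = [
            {"comparisons": ",".join(sorted(k)), "n_items": v}
            for k, v in sorted(self.region_counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["comparisons", "n_items"])


def classify_parallelism(sets: dict[str, set], level: str = "gene") -> ParallelismReport:
    """Venn classification of per-comparison item sets (genes or SNPs).

    Items shared by two or more comparisons evidence parallel evolution at
    this level; items exclusive to one comparison, where other comparisons
    hit different items for the same phenotype, evidence convergence.
    """
    labels = list(sets)
    universe = sorted(set().union(*sets.values()), key=str)
    membership = pd.DataFrame(
        {lab: [item in sets[lab] for item in universe] for lab in labels},
        index=pd.Index(universe, name="item", tupleize_cols=False),
    )
    region_counts: dict[frozenset, int] = {}
    n_member = membership.sum(axis=1)
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            key = frozenset(combo)
            in_combo = membership[list(combo)].all(axis=1) & (n_member == r)
            cnt = int(in_combo.sum())
            if cnt:
                region_counts[key] = cnt
    return ParallelismReport(
        level=level,
        membership=membership,
        region_counts=region_counts,
        union_size=len(universe),
        shared_two_plus=int((n_member >= 2).sum()),
        shared_all=int((n_member == len(labels)).sum()),
    )


def category_sharing(
    report: ParallelismReport, categories: dict[str, str]
) -> pd.DataFrame:
    """Per gene category: total, shared by >= 2 comparisons, exclusive to 1.

    ``categories`` maps gene id -> category label (e.g. timing /
    energetics / morphology); genes without a category are summarised
    under "uncategorized".
    """
    n_member = report.membership.sum(axis=1)
    rows = {}
    for item in report.membership.index:
        cat = categories.get(item, "uncategorized")
        d = rows.setdefault(cat, {"category": cat, "total": 0, "shared_two_plus": 0, "single": 0})
        d["total"] += 1
        if n_member[item] >= 2:
            d["shared_two_plus"] += 1
        elif n_member[item] == 1:
            d["single"] += 1
    return pd.DataFrame(
        sorted(rows.values(), key=lambda d: d["category"]),
        columns=["category", "total", "shared_two_plus", "single"],
    )


def directionality_concordance(
    shared_items: pd.DataFrame,
    memberships: pd.DataFrame,
    xpehh_by_comparison: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, float]:
    """Sign agreement of XP-EHH across the comparisons sharing each item.

    ``shared_items`` holds chrom/start/end plus an ``item`` key column;
    ``memberships`` is the item x comparison boolean frame.  For each
    sharing comparison the sign is taken at the item's best (largest
    |standardized score|) significant XP-EHH site inside the interval;
    with no significant site the sign is undetermined and the item is
    excluded from the concordant fraction's denominator.

    With residents on side A of every scan, all-positive signs mean the
    sweep acted in the resident populations of every sharing comparison.
    """
    rows = []
    n_concordant = 0
    n_determined = 0
    for row in shared_items.itertuples(index=False):
        labels = [c for c in memberships.columns if memberships.at[row.item, c]]
        signs = {}
        for lab in labels:
            xp = xpehh_by_comparison[lab]
            inside = (
                (xp["chrom"] == row.chrom)
                & (xp["pos"] - 1 >= row.start)
                & (xp["pos"] - 1 < row.end)
                & xp["significant"]
            )
            if not inside.any():
                signs[lab] = 0  # undetermined
                continue
            sub = xp.loc[inside]
            best = sub.loc[sub["z"].abs().idxmax()]
            signs[lab] = 1 if best["z"] > 0 else -1
        determined = all(s != 0 for s in signs.values()) and len(signs) >= 2
        concordant = determined and len(set(signs.values())) == 1
        if determined:
            n_determined += 1
            n_concordant += int(concordant)
        else:
            logger.info("directionality: %s has undetermined sign in some comparison", row.item)
        rows.append(
            {
                "item": row.item,
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "signs": ";".join(f"{lab}:{s:+d}" if s else f"{lab}:NA" for lab, s in signs.items()),
                "determined": determined,
                "concordant": concordant,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["item", "chrom", "start", "end", "signs", "determined", "concordant"],
    )
    fraction = n_concordant / n_determined if n_determined else float("nan")
    return frame, fraction


def functional_categorize(
    items: pd.DataFrame, annotation: pd.DataFrame, max_dist_bp: int = 25_000
) -> pd.DataFrame:
    """Simplified functional category per item.

    genic: overlaps a gene interval; proximal-regulatory: within
    ``max_dist_bp`` of a gene but not overlapping; intergenic: otherwise.
    """
    items = _as_intervals(items)
    hits = genes_near(items, annotation, max_dist_bp)
    key = lambda df: list(zip(df["chrom"], df["start"], df["end"]))
    best: dict[tuple, int] = {}
    for k, dist in zip(key(hits), hits["distance"]):
        best[k] = min(best.get(k, dist), dist)
    cats = []
    for k in key(items):
        if k not in best:
            cats.append("intergenic")
        elif best[k] == 0:
            cats.append("genic")
        else:
            cats.append("proximal-regulatory")
    out = items.copy()
    out["category"] = cats
    return out
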