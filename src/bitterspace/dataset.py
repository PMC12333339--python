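"""Taste-annotated peptide records and the two-part space analysis.

A :class:`PeptideRecord` is one entry of a bitter-peptide collection:
the sequence in three notations, a closed taste vocabulary (bitter /
nonbitter / not_tested, where nonbitter covers both taste-active and
taste-inactive reports), a conflict flag for discrepant sensory data,
the bitter taste threshold (BTT, mmol/L) for bitter entries, sparse
TAS2R annotations, a coarse food-source category, and the modification
group (1 canonical, 2 cyclic, 3 salts/esters, 4 pyroglutamyl, 5
gamma-Glu/Asp, 6 Nle/Nva, 7 other).

The analysis splits records into canonical and modified sets, tabulates
length and amino-acid composition per taste class, places records in the
two descriptor planes (Q value vs length; SlogP vs monoisotopic MW),
counts taste classes on either side of a hydrophobicity threshold, and
summarizes BTTs and receptor coverage. All operations are order-
invariant and conserve record counts (exclusions are enumerated, never
silent).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import descriptors, notation, scoring
from .monomers import MonomerLibrary, core_library

__all__ = [
    "PeptideRecord",
    "SpacePoint",
    "EnrichmentSummary",
    "DatasetError",
    "TAS2R_VOCABULARY",
    "read_records",
    "write_records",
    "records_to_frame",
    "split_canonical",
    "length_distribution",
    "aa_composition",
    "space_points",
    "threshold_enrichment",
    "btt_summary",
    "receptor_coverage",
    "load_tas2r_reference",
    "correlation_report",
    "export_space_plot",
]

TASTE_VALUES = ("bitter", "nonbitter", "not_tested")
SOURCE_VALUES = ("animal", "plant", "yeast", "mixed", "other")

#: Peptide-sensitive human bitter taste receptors: the nine with
#: tabulated peptide agonists plus TAS2R7/38/41 reported peptide-sensitive.
TAS2R_VOCABULARY = frozenset(
    {
        "TAS2R1",
        "TAS2R4",
        "TAS2R7",
        "TAS2R8",
        "TAS2R14",
        "TAS2R16",
        "TAS2R20",
        "TAS2R38",
        "TAS2R39",
        "TAS2R41",
        "TAS2R43",
        "TAS2R46",
    }
)

MANDATORY_COLUMNS = ["id", "fasta", "canonical", "taste", "mod_group"]
STANDARD_COLUMNS = [
    "id",
    "fasta",
    "helm",
    "biln",
    "canonical",
    "taste",
    "conflict",
    "btt_mmol_L",
    "receptors",
    "source",
    "mod_group",
    "references",
]


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRecord:
    """One collection entry; see module docstring for field semantics."""

    id: str
    fasta: str
    helm: str = ""
    biln: str = ""
    canonical: bool = True
    taste: str = "not_tested"
    conflict: bool = False
    btt: float | None = None
    receptors: tuple[str, ...] = ()
    source: str = "other"
    mod_group: int = 1
    references: str = ""
    extra: dict = field(default_factory=dict, compare=False)

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        problems = []
        if not self.id:
            problems.append("empty id")
        if self.taste not in TASTE_VALUES:
            problems.append(f"taste {self.taste!r} not in {TASTE_VALUES}")
        if not 1 <= self.mod_group <= 7:
            problems.append(f"mod_group {self.mod_group} outside 1-7")
        if self.canonical != (self.mod_group == 1):
            problems.append(
                f"canonical={self.canonical} inconsistent with mod_group={self.mod_group}"
            )
        if self.btt is not None:
            if self.taste != "bitter":
                problems.append("btt present but taste is not bitter")
            elif not self.btt > 0:
                problems.append(f"btt {self.btt} not positive")
        unknown = set(self.receptors) - TAS2R_VOCABULARY
        if unknown:
            problems.append(f"unknown receptor id(s) {sorted(unknown)}")
        if self.source not in SOURCE_VALUES:
            problems.append(f"source {self.source!r} not in {SOURCE_VALUES}")
        return problems


@dataclass(frozen=True)
class SpacePoint:
    """One record's coordinates in a descriptor plane."""

    id: str
    x: float
    y: float
    axes: tuple[str, str]
    taste: str
    mod_group: int
    btt: float | None = None
    receptors: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnrichmentSummary:
    """Counts of taste classes on either side of a threshold on one axis."""

    threshold: float
    axis: str
    bitter_above: int
    nonbitter_above: int
    bitter_below: int
    nonbitter_below: int
    excluded: int = 0  # points without a bitter/nonbitter label

    @property
    def total(self) -> int:
        return (
            self.bitter_above
            + self.nonbitter_above
            + self.bitter_below
            + self.nonbitter_below
            + self.excluded
        )

    @property
    def bitter_fraction_above(self) -> float:
        denom = self.bitter_above + self.nonbitter_above
        return self.bitter_above / denom if denom else float("nan")

    @property
    def bitter_fraction_below(self) -> float:
        denom = self.bitter_below + self.nonbitter_below
        return self.bitter_below / denom if denom else float("nan")


# --------------------------------------------------------------------------
# table I/O


def _record_from_row(row: dict, rownum: int) -> tuple[PeptideRecord | None, list[str]]:
    def text(key, default=""):
        v = row.get(key)
        return default if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)

    btt_raw = row.get("btt_mmol_L")
    btt = None
    if btt_raw not in (None, ""):
        try:
            btt = float(btt_raw)
            if np.isnan(btt):
                btt = None
        except (TypeError, ValueError):
            return None, [f"row {rownum}: btt_mmol_L {btt_raw!r} is not numeric"]
    receptors = tuple(r for r in text("receptors").split(";") if r)
    try:
        record = PeptideRecord(
            id=text("id"),
            fasta=text("fasta"),
            helm=text("helm"),
            biln=text("biln"),
            canonical=str(row.get("canonical", "1")) in ("1", "True", "true"),
            taste=text("taste", "not_tested"),
            conflict=str(row.get("conflict", "0")) in ("1", "True", "true"),
            btt=btt,
            receptors=receptors,
            source=text("source", "other"),
            mod_group=int(row.get("mod_group", 1)),
            references=text("references"),
            extra={k: row[k] for k in row if k not in STANDARD_COLUMNS},
        )
    except (TypeError, ValueError) as exc:
        return None, [f"row {rownum}: {exc}"]
    problems = [f"row {rownum}: {p}" for p in record.validate()]
    return record, problems


def read_records(path) -> list[PeptideRecord]:
    """Read a tab-separated record table. Unknown columns are preserved in
    ``extra``; any invariant violation is reported with its row number."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MANDATORY_COLUMNS) - set(frame.columns)
    if missing:
        raise DatasetError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    records, problems = [], []
    for i, row in enumerate(frame.to_dict(orient="records"), start=2):  # 1 = header
        rec, probs = _record_from_row(
            {k: (v if v != "" else None) for k, v in row.items()}, i
        )
        problems.extend(probs)
        if rec is not None and not probs:
            records.append(rec)
    if problems:
        raise DatasetError(f"{path}: invalid records:\n" + "\n".join(problems))
    return records


def records_to_frame(records: list[PeptideRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "fasta": r.fasta,
            "helm": r.helm,
            "biln": r.biln,
            "canonical": int(r.canonical),
            "taste": r.taste,
            "conflict": int(r.conflict),
            "btt_mmol_L": "" if r.btt is None else repr(r.btt),
            "receptors": ";".join(r.receptors),
            "source": r.source,
            "mod_group": r.mod_group,
            "references": r.references,
        }
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def write_records(records: list[PeptideRecord], path) -> None:
    """Write records as the tab-separated table read by :func:`read_records`
    (lossless round trip)."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# workflow part 1: dataset analysis


def split_canonical(
    records: list[PeptideRecord],
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Partition into (canonical, modified), preserving order."""
    canonical = [r for r in records if r.canonical]
    modified = [r for r in records if not r.canonical]
    return canonical, modified


def _canonical_seq(record: PeptideRecord) -> str:
    seq = record.fasta
    bad = set(seq) - scoring.CANONICAL_RESIDUES
    if bad:
        raise DatasetError(
            f"record {record.id}: non-canonical symbols {sorted(bad)} in a canonical record"
        )
    return seq


def length_distribution(records: list[PeptideRecord]) -> pd.DataFrame:
    """Count canonical peptides per (length, taste); counts sum to the
    input size."""
    rows = [
        {"length": len(_canonical_seq(r)), "taste": r.taste} for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=["length", "taste", "count"])
    out = (
        pd.DataFrame(rows)
        .value_counts(["length", "taste"])
        .rename("count")
        .reset_index()
        .sort_values(["length", "taste"], ignore_index=True)
    )
    return out


def aa_composition(records: list[PeptideRecord], filter=None) -> pd.DataFrame:
    """Count residue occurrences per (residue, taste) over canonical
    records; an optional predicate (record -> bool) filters records first."""
    rows = []
    for r in records:
        if filter is not None and not filter(r):
            continue
        for residue in _canonical_seq(r):
            rows.append({"residue": residue, "taste": r.taste})
    if not rows:
        return pd.DataFrame(columns=["residue", "taste", "count"])
    return (
        pd.DataFrame(rows)
        .value_counts(["residue", "taste"])
        .rename("count")
        .reset_index()
        .sort_values(["residue", "taste"], ignore_index=True)
    )


# --------------------------------------------------------------------------
# workflow part 2: descriptor space

AXES_Q_LENGTH = ("q_value", "length")
AXES_LOGP_MW = ("logp", "exact_mw")


def space_points(
    records: list[PeptideRecord],
    axes: tuple[str, str] = AXES_Q_LENGTH,
    lib: MonomerLibrary | None = None,
) -> tuple[list[SpacePoint], list[tuple[str, str]]]:
    """Compute one point per scorable record on the requested axis pair.

    Returns ``(points, exclusions)`` where exclusions are ``(record id,
    reason)`` pairs — e.g. modified records on the Q axis, since Q is
    defined only for canonical sequences.
    """
    if axes not in (AXES_Q_LENGTH, AXES_LOGP_MW):
        raise DatasetError(f"unknown axis pair {axes!r}")
    lib = lib or core_library()
    points, exclusions = [], []
    for r in records:
        try:
            if axes == AXES_Q_LENGTH:
                if not r.canonical:
                    raise DatasetError("Q value undefined for modified peptides")
                x = scoring.q_value(_canonical_seq(r)).value
                y = float(len(r.fasta))
            else:
                seq = notation.parse_fasta_extended(r.fasta, lib)
                graph = notation.assemble(seq, lib)
                x = descriptors.logp(graph)
                y = descriptors.exact_mw(graph)
        except (ValueError, KeyError) as exc:
            exclusions.append((r.id, str(exc)))
            continue
        points.append(
            SpacePoint(
                id=r.id,
                x=x,
                y=y,
                axes=axes,
                taste=r.taste,
                mod_group=r.mod_group,
                btt=r.btt,
                receptors=r.receptors,
            )
        )
    return points, exclusions


def threshold_enrichment(
    points: list[SpacePoint], threshold: float, axis: str = "x"
) -> EnrichmentSummary:
    """Partition points at a threshold on one axis and count taste classes.

    The four counts plus the excluded (unlabelled) count sum to the input
    size; 'above' means strictly greater than the threshold.
    """
    if axis not in ("x", "y"):
        raise DatasetError("axis must be 'x' or 'y'")
    axis_pairs = {p.axes for p in points}
    if len(axis_pairs) > 1:
        raise DatasetError(f"points mix axis pairs: {sorted(axis_pairs)}")
    counts = {"bitter_above": 0, "nonbitter_above": 0, "bitter_below": 0, "nonbitter_below": 0}
    excluded = 0
    for p in points:
        if p.taste not in ("bitter", "nonbitter"):
            excluded += 1
            continue
        side = "above" if (p.x if axis == "x" else p.y) > threshold else "below"
        counts[f"{p.taste}_{side}"] += 1
    axis_name = (points[0].axes[0 if axis == "x" else 1]) if points else axis
    return EnrichmentSummary(
        threshold=threshold, axis=axis_name, excluded=excluded, **counts
    )


DEFAULT_BTT_EDGES = (1.0, 10.0, 100.0)


def btt_summary(
    records: list[PeptideRecord], edges: tuple[float, ...] = DEFAULT_BTT_EDGES
) -> dict:
    """Summarize bitter taste thresholds of the btt-bearing records: band
    counts at the given edges (default <1, 1-10, 10-100, >100 mmol/L),
    quantiles, and the extreme records."""
    with_btt = [(r.id, r.btt) for r in records if r.btt is not None]
    n = len(with_btt)
    bands = []
    lo = None
    for hi in list(edges) + [None]:
        label = (
            f"<{hi}" if lo is None else (f"{lo}-{hi}" if hi is not None else f">{lo}")
        )
        count = sum(
            1
            for _, v in with_btt
            if (lo is None or v >= lo) and (hi is None or v < hi)
        )
        bands.append({"band_mmol_L": label, "count": count})
        lo = hi
    values = np.array([v for _, v in with_btt]) if with_btt else np.array([])
    summary = {
        "n": n,
        "bands": pd.DataFrame(bands),
        "quantiles": {
            q: float(np.quantile(values, q)) if n else float("nan")
            for q in (0.25, 0.5, 0.75)
        },
    }
    if n:
        min_id, min_v = min(with_btt, key=lambda t: t[1])
        max_id, max_v = max(with_btt, key=lambda t: t[1])
        summary.update(
            min={"id": min_id, "btt_mmol_L": min_v},
            max={"id": max_id, "btt_mmol_L": max_v},
            fraction_below_10=float(np.mean(values < 10.0)),
        )
    return summary


def load_tas2r_reference() -> dict[str, tuple[str, ...]]:
    """The shipped receptor -> agonist-peptide reference table."""
    ref = importlib.resources.files("bitterspace").joinpath("data/tas2r_peptides.tsv")
    out: dict[str, tuple[str, ...]] = {}
    for line in ref.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("receptor\t"):
            continue
        receptor, peptides = line.split("\t")
        out[receptor] = tuple(p for p in peptides.split(",") if p)
    return out


def receptor_coverage(
    records: list[PeptideRecord] | None = None,
    reference: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Count peptides per receptor. With ``records``, counts come from the
    record annotations (a peptide on several receptors counts toward
    each); with only ``reference``, from the reference map itself."""
    if records is None and reference is None:
        raise DatasetError("receptor_coverage needs records or a reference map")
    if reference is not None:
        unknown = set(reference) - TAS2R_VOCABULARY
        if unknown:
            raise DatasetError(f"unknown receptor id(s) in reference: {sorted(unknown)}")
    if records is not None:
        counts = dict.fromkeys(sorted(reference or TAS2R_VOCABULARY), 0)
        for r in records:
            for receptor in r.receptors:
                if receptor not in TAS2R_VOCABULARY:
                    raise DatasetError(
                        f"record {r.id}: unknown receptor id {receptor!r}"
                    )
                counts[receptor] = counts.get(receptor, 0) + 1
    else:
        counts = {rec: len(peps) for rec, peps in reference.items()}
    return (
        pd.DataFrame(
            [{"receptor": k, "peptide_count": v} for k, v in counts.items()]
        )
        .sort_values(["peptide_count", "receptor"], ascending=[False, True])
        .reset_index(drop=True)
    )


def correlation_report(points_a, points_b) -> tuple[float, float, str]:
    """Pearson correlations of two paired-value sets and their comparison.

    Each argument is a sequence of (x, y) pairs or :class:`SpacePoint`.
    """

    def pearson(pairs):
        xy = np.array(
            [(p.x, p.y) if isinstance(p, SpacePoint) else tuple(p) for p in pairs],
            dtype=float,
        )
        if len(xy) < 3:
            raise DatasetError("need at least 3 paired values")
        if np.isclose(xy[:, 0].std(), 0) or np.isclose(xy[:, 1].std(), 0):
            raise DatasetError("correlation undefined: zero variance")
        return float(stats.pearsonr(xy[:, 0], xy[:, 1]).statistic)

    r_a, r_b = pearson(points_a), pearson(points_b)
    if r_a > r_b:
        comparison = "first stronger"
    elif r_b > r_a:
        comparison = "second stronger"
    else:
        comparison = "equal"
    return r_a, r_b, comparison


# --------------------------------------------------------------------------
# plotting

_TASTE_COLORS = {"bitter": "#2e8b57", "nonbitter": "#4169e1", "not_tested": "#999999"}


def export_space_plot(points: list[SpacePoint], path, color_by: str = "taste"):
    """Scatter a descriptor plane to ``path`` (PNG/SVG by extension),
    colored by taste, BTT, receptor, or modification group. Bitter is
    green, nonbitter blue, matching the collection's convention."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not points:
        raise DatasetError("no points to plot")
    if color_by not in ("taste", "btt", "receptor", "mod_group"):
        raise DatasetError(f"unknown color_by {color_by!r}")
    axes = points[0].axes
    fig, ax = plt.subplots(figsize=(6, 5))
    if color_by == "btt":
        with_btt = [p for p in points if p.btt is not None]
        if not with_btt:
            raise DatasetError("color_by='btt' but no point carries a btt value")
        sc = ax.scatter(
            [p.x for p in with_btt],
            [p.y for p in with_btt],
            c=np.log10([p.btt for p in with_btt]),
            cmap="Greens_r",
            s=14,
        )
        fig.colorbar(sc, ax=ax, label="log10 BTT (mmol/L)")
    else:
        if color_by == "taste":
            groups = {t: _TASTE_COLORS[t] for t in ("bitter", "nonbitter", "not_tested")}
            key = lambda p: p.taste
        elif color_by == "mod_group":
            cmap = plt.get_cmap("tab10")
            groups = {g: cmap((g - 1) % 10) for g in range(1, 8)}
            key = lambda p: p.mod_group
        else:  # receptor: first annotated receptor per point
            receptors = sorted({p.receptors[0] for p in points if p.receptors})
            if not receptors:
                raise DatasetError("color_by='receptor' but no point carries receptors")
            cmap = plt.get_cmap("tab20")
            groups = {rec: cmap(i % 20) for i, rec in enumerate(receptors)}
            key = lambda p: (p.receptors[0] if p.receptors else None)
        for value, color in groups.items():
            sel = [p for p in points if key(p) == value]
            if sel:
                ax.scatter(
                    [p.x for p in sel],
                    [p.y for p in sel],
                    color=color,
                    s=14,
                    label=str(value),
                )
        ax.legend(title=color_by, fontsize=8)
    ax.set_xlabel(axes[0])
    ax.set_ylabel(axes[1])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
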