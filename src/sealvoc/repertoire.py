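"""Call taxonomy, bout segmentation and repertoire summaries.

Hawaiian monk seals produce six elemental underwater call types (Croak,
Growl, Moan, Rumble, Whoop, Whine) and combine them, without intervening
silence, into combinational calls whose labels concatenate the unit names
(e.g. ``MoanGrowl``).  Two further units, Hum and Grunt, occur only
embedded inside combinational calls and never as stand-alone calls.
Bouts are runs of two or more calls separated by less than 3 s of
silence, assumed to come from a single caller when call structure and
amplitude are consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .util import round_half_up

__all__ = [
    "ELEMENTAL_UNITS",
    "EMBEDDED_ONLY_UNITS",
    "ALL_UNITS",
    "CallTypeLabel",
    "CallAnnotation",
    "Bout",
    "decompose_label",
    "apply_duration_rule",
    "merge_adjacent",
    "segment_bouts",
    "screen_for_measurement",
    "filter_min_exemplars",
    "RepertoireSummary",
    "summarize_counts",
    "summarize_repertoire",
    "load_published_call_counts",
    "load_call_feature_stats",
    "read_call_log",
    "write_call_log",
]

#: Units that occur as stand-alone (elemental) calls.
ELEMENTAL_UNITS = ("Croak", "Growl", "Moan", "Rumble", "Whoop", "Whine")
#: Units only ever observed embedded within combinational calls.
EMBEDDED_ONLY_UNITS = ("Hum", "Grunt")
ALL_UNITS = ELEMENTAL_UNITS + EMBEDDED_ONLY_UNITS
# longest-first so greedy prefix matching is unambiguous
_UNITS_BY_LENGTH = tuple(sorted(ALL_UNITS, key=len, reverse=True))

#: Quality score and SNR screening thresholds for measurability.
QUALITY_REQUIRED = 3
SNR_THRESHOLD_DB = 10.5
#: Maximum silent gap (s) between calls within a bout.
BOUT_GAP_S = 3.0
#: Croak/Growl duration boundary (s): < 0.5 is a Croak.
CROAK_GROWL_BOUNDARY_S = 0.5


@dataclass(frozen=True)
class CallTypeLabel:
    """A parsed call-type label: ordered elemental units."""

    label: str
    units: tuple[str, ...]

    @property
    def is_combinational(self) -> bool:
        return len(self.units) >= 2


def decompose_label(label: str) -> CallTypeLabel:
    """Parse a call-type label into its ordered unit names.

    Greedy longest-prefix parse over the eight unit names; repeats are
    allowed (``MoanGrowlMoanWhoop``).  Raises on unparseable residue,
    naming the offending suffix, and on single-unit Hum/Grunt labels,
    which never occur as stand-alone calls.
    """
    if not label:
        raise ValueError("empty call-type label")
    units: list[str] = []
    pos = 0
    while pos < len(label):
        for unit in _UNITS_BY_LENGTH:
            if label.startswith(unit, pos):
                units.append(unit)
                pos += len(unit)
                break
        else:
            raise ValueError(
                f"cannot parse call-type label {label!r}: "
                f"unrecognized suffix {label[pos:]!r}"
            )
    if len(units) == 1 and units[0] in EMBEDDED_ONLY_UNITS:
        raise ValueError(
            f"{units[0]!r} never occurs as a stand-alone call type"
        )
    return CallTypeLabel(label=label, units=tuple(units))


def apply_duration_rule(duration: float) -> str:
    """Croak/Growl duration rule: calls under 0.5 s are Croaks.

    The boundary itself (exactly 0.5 s) is a Growl — the published rule
    is strict only for the Croak side.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    return "Croak" if duration < CROAK_GROWL_BOUNDARY_S else "Growl"


@dataclass
class CallAnnotation:
    """One detected call in a call log.

    ``start``/``end`` are naive local timestamps (HST semantics).
    ``quality`` is the three-point subjective scale (3 = loud/clear).
    """

    site: str
    start: pd.Timestamp
    end: pd.Timestamp
    label: str
    deployment_id: str = ""
    quality: int = 3
    snr: float | None = None
    bout_id: int | None = None
    amplitude_class: int | None = None

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if not self.start < self.end:
            raise ValueError("annotation start must precede end")
        if self.quality not in (1, 2, 3):
            raise ValueError("quality must be 1, 2 or 3")

    @property
    def duration(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class Bout:
    """Two or more calls with every silent gap under the 3 s threshold."""

    members: list[CallAnnotation]
    site: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a bout needs at least two member calls")


def _sorted(annotations: list[CallAnnotation]) -> list[CallAnnotation]:
    return sorted(annotations, key=lambda a: (a.site, a.start, a.end))


def merge_adjacent(
    annotations: list[CallAnnotation], max_gap: float = 0.1
) -> list[CallAnnotation]:
    """Combine sequential calls with no intervening ambient noise.

    Runs of calls whose inter-call gap is at most ``max_gap`` seconds are
    replaced by a single annotation whose label concatenates the member
    labels and whose span covers the run.  Calls with differing
    ``amplitude_class`` are never merged (they are treated as different
    callers), and merging never crosses sites.
    """
    out: list[CallAnnotation] = []
    run: list[CallAnnotation] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            first = run[0]
            out.append(
                replace(
                    first,
                    end=run[-1].end,
                    label="".join(a.label for a in run),
                    quality=min(a.quality for a in run),
                    snr=None,
                )
            )
        run.clear()

    for ann in _sorted(annotations):
        if run:
            prev = run[-1]
            gap = (ann.start - prev.end).total_seconds()
            same_caller = (
                ann.site == prev.site
                and (
                    ann.amplitude_class is None
                    or prev.amplitude_class is None
                    or ann.amplitude_class == prev.amplitude_class
                )
            )
            if gap <= max_gap and same_caller:
                run.append(ann)
                continue
        flush()
        run.append(ann)
    flush()
    return out


def segment_bouts(
    annotations: list[CallAnnotation], gap_threshold: float = BOUT_GAP_S
) -> tuple[list[Bout], list[CallAnnotation]]:
    """Segment time-sorted calls into bouts and left-over singletons.

    A bout is a maximal run in which every silent gap (next start minus
    previous end) is strictly less than ``gap_threshold`` seconds; runs
    of length one remain singletons.  Member ``bout_id`` fields are set
    on the returned annotations.  Segmentation respects sites and, when
    given, amplitude classes (parallel overlapping runs at different
    amplitudes belong to different callers).
    """
    bouts: list[Bout] = []
    singletons: list[CallAnnotation] = []
    next_id = 1

    def keyfn(a: CallAnnotation):
        return (a.site, a.amplitude_class)

    groups: dict = {}
    for ann in _sorted(annotations):
        groups.setdefault(keyfn(ann), []).append(ann)

    for _, group in sorted(groups.items(), key=lambda kv: str(kv[0])):
        run: list[CallAnnotation] = []

        def flush() -> None:
            nonlocal next_id
            if not run:
                return
            if len(run) >= 2:
                for a in run:
                    a.bout_id = next_id
                bouts.append(
                    Bout(
                        members=list(run),
                        site=run[0].site,
                        start=run[0].start,
                        end=run[-1].end,
                    )
                )
                next_id += 1
            else:
                run[0].bout_id = None
                singletons.append(run[0])
            run.clear()

        for ann in group:
            if run and (ann.start - run[-1].end).total_seconds() < gap_threshold:
                run.append(ann)
            else:
                flush()
                run.append(ann)
        flush()
    return bouts, singletons


def screen_for_measurement(
    annotations: list[CallAnnotation],
    quality: int = QUALITY_REQUIRED,
    snr_threshold: float = SNR_THRESHOLD_DB,
) -> list[CallAnnotation]:
    """Retain calls suitable for quantitative measurement.

    Keeps calls rated at the required quality whose SNR strictly exceeds
    the threshold (default 10.5 dB).  Calls with no SNR are excluded with
    a warning.
    """
    kept = []
    n_missing = 0
    for a in annotations:
        if a.quality != quality:
            continue
        if a.snr is None or (isinstance(a.snr, float) and np.isnan(a.snr)):
            n_missing += 1
            continue
        if a.snr > snr_threshold:
            kept.append(a)
    if n_missing:
        warnings.warn(
            f"{n_missing} quality-{quality} calls had no SNR and were excluded",
            stacklevel=2,
        )
    return kept


def filter_min_exemplars(labels, minimum: int = 5) -> list[str]:
    """Call types with at least ``minimum`` measured exemplars.

    ``labels`` is any iterable of per-call type labels; returns the
    retained type names sorted by descending count.
    """
    counts = pd.Series(list(labels)).value_counts()
    return list(counts[counts >= minimum].index)


@dataclass
class RepertoireSummary:
    """Per-type, per-site detection counts with repertoire breakdowns."""

    table: pd.DataFrame  # counts per type x site, plus total / pct columns
    grand_total: int
    combinational_types: list[str]
    combinational_total: int
    elemental_total: int

    @property
    def n_combinational_types(self) -> int:
        return len(self.combinational_types)

    def percent_of_total(self, vocal_type: str, ndigits: int = 1) -> float:
        """Share of all detections for one type, rounded half-up."""
        count = int(self.table.loc[vocal_type, "total"])
        return round_half_up(100.0 * count / self.grand_total, ndigits)

    def percent_of_combinational(self, vocal_type: str, ndigits: int = 0) -> float:
        count = int(self.table.loc[vocal_type, "total"])
        return round_half_up(100.0 * count / self.combinational_total, ndigits)


def summarize_counts(counts: pd.DataFrame) -> RepertoireSummary:
    """Build a repertoire summary from a per-type x per-site count matrix.

    ``counts`` is indexed by vocal type with one integer column per site.
    Adds a ``total`` column, the percent of the grand total (1 decimal,
    half-up; types under 0.1% flagged as '—' in ``pct_display``), and
    classifies each type as elemental or combinational via the label
    parser.
    """
    counts = counts.astype(int)
    table = counts.copy()
    table["total"] = counts.sum(axis=1)
    grand = int(table["total"].sum())
    if grand == 0:
        table["pct_of_total"] = 0.0
        table["pct_display"] = "—"
        table["is_combinational"] = [
            decompose_label(t).is_combinational for t in table.index
        ]
        return RepertoireSummary(table, 0, [], 0, 0)
    pct = [round_half_up(100.0 * c / grand, 1) for c in table["total"]]
    table["pct_of_total"] = pct
    table["pct_display"] = [f"{p}%" if p >= 0.1 else "—" for p in pct]
    combo_mask = [decompose_label(t).is_combinational for t in table.index]
    table["is_combinational"] = combo_mask
    combo_types = list(table.index[table["is_combinational"]])
    combo_total = int(table.loc[combo_types, "total"].sum())
    return RepertoireSummary(
        table=table,
        grand_total=grand,
        combinational_types=combo_types,
        combinational_total=combo_total,
        elemental_total=grand - combo_total,
    )


def summarize_repertoire(annotations: list[CallAnnotation]) -> RepertoireSummary:
    """Repertoire summary straight from a call log."""
    if not annotations:
        return summarize_counts(pd.DataFrame(dtype=int))
    df = pd.DataFrame({"label": [a.label for a in annotations],
                       "site": [a.site for a in annotations]})
    counts = (
        df.groupby(["label", "site"]).size().unstack(fill_value=0).sort_index()
    )
    return summarize_counts(counts)


# ---------------------------------------------------------------------------
# Packaged reference tables and call-log I/O

def _data_path(name: str):
    from importlib import resources

    return resources.files("sealvoc.data").joinpath(name)


def load_published_call_counts() -> pd.DataFrame:
    """Published per-type, per-site detection counts for the five-site
    Hawaiian monk seal survey (25 vocal types; grand total 23 416)."""
    with _data_path("call_counts_by_site.csv").open() as fh:
        return pd.read_csv(fh, index_col="vocal_type")


def load_call_feature_stats() -> pd.DataFrame:
    """Published mean/s.d. acoustic parameters and sample sizes for the
    10 vocal types with at least five measurable exemplars."""
    with _data_path("call_feature_stats.csv").open() as fh:
        return pd.read_csv(fh, index_col="vocal_type")


_LOG_COLUMNS = [
    "site", "deployment_id", "start_iso", "end_iso",
    "label", "quality", "snr_db", "amplitude_class",
]


def read_call_log(path) -> list[CallAnnotation]:
    """Read a comma-separated call log (one row per detected call)."""
    df = pd.read_csv(path)
    missing = [c for c in _LOG_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing call-log columns {missing}")
    anns = []
    for _, row in df.iterrows():
        snr = row.get("snr_db")
        amp = row.get("amplitude_class")
        anns.append(
            CallAnnotation(
                site=str(row["site"]),
                deployment_id=str(row.get("deployment_id", "")),
                start=pd.Timestamp(row["start_iso"]),
                end=pd.Timestamp(row["end_iso"]),
                label=str(row["label"]),
                quality=int(row["quality"]),
                snr=None if pd.isna(snr) else float(snr),
                amplitude_class=None if pd.isna(amp) else int(amp),
            )
        )
    return anns


def write_call_log(path, annotations: list[CallAnnotation]) -> None:
    pd.DataFrame(
        {
            "site": [a.site for a in annotations],
            "deployment_id": [a.deployment_id for a in annotations],
            "start_iso": [a.start.isoformat() for a in annotations],
            "end_iso": [a.end.isoformat() for a in annotations],
            "label": [a.label for a in annotations],
            "quality": [a.quality for a in annotations],
            "snr_db": [a.snr for a in annotations],
            "amplitude_class": [a.amplitude_class for a in annotations],
        }
    ).to_csv(path, index=False)
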