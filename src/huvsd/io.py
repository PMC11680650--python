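"""Reading count tables and dichotomising confidence ratings.

The canonical input is a delimited text table with header
``participant_id,hits,false_alarms,signal_trials,noise_trials`` (comma by
default, tab accepted), one row per participant.  Rating data arrive in
long format (``participant_id,trial_type,rating,scale_max``) and are
reduced to counts by a midpoint dichotomisation rule.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import TrialCounts

__all__ = [
    "read_counts",
    "write_counts",
    "dichotomise",
    "counts_from_ratings",
    "read_ratings",
]

_COLUMNS = ["participant_id", "hits", "false_alarms", "signal_trials", "noise_trials"]


class CountTableError(ValueError):
    """Malformed count table; carries per-row diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("malformed count table:\n" + "\n".join(problems))


def _sniff_delimiter(path: Path) -> str:
    first = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in first else ","


def read_counts(path: str | Path) -> list[TrialCounts]:
    """Parse a per-participant count table into TrialCounts.

    Raises :class:`CountTableError` listing every offending row if any row
    has non-integer fields or counts exceeding their trial totals.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise CountTableError([f"missing columns: {', '.join(missing)}"])
    problems: list[str] = []
    counts: list[TrialCounts] = []
    for idx, row in frame.iterrows():
        try:
            counts.append(
                TrialCounts(
                    participant_id=row["participant_id"],
                    h=int(row["hits"]),
                    f=int(row["false_alarms"]),
                    s=int(row["signal_trials"]),
                    n=int(row["noise_trials"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {idx} (participant {row['participant_id']!r}): {exc}")
    if problems:
        raise CountTableError(problems)
    return counts


def write_counts(counts: list[TrialCounts], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in counts],
            "hits": [t.h for t in counts],
            "false_alarms": [t.f for t in counts],
            "signal_trials": [t.s for t in counts],
            "noise_trials": [t.n for t in counts],
        }
    ).to_csv(path, index=False)


def dichotomise(rating: int, scale_max: int, threshold: int | None = None) -> bool:
    """Map a confidence rating to a binary Yes response.

    By the midpoint rule a rating is a Yes iff it is <= threshold, with the
    threshold defaulting to scale_max // 2 (so 3 on a 1-6 scale).
    """
    if not (1 <= rating <= scale_max):
        raise ValueError(f"rating {rating} outside 1..{scale_max}")
    if threshold is None:
        threshold = scale_max // 2
    return rating <= threshold


def read_ratings(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    needed = {"participant_id", "trial_type", "rating", "scale_max"}
    missing = needed - set(frame.columns)
    if missing:
        raise CountTableError([f"missing columns: {', '.join(sorted(missing))}"])
    return frame


def counts_from_ratings(
    ratings: pd.DataFrame, threshold: int | None = None
) -> list[TrialCounts]:
    """Aggregate long-format rating trials into per-participant counts.

    ``trial_type`` must be 'signal' or 'noise'; a Yes on a signal trial is
    a hit, on a noise trial a false alarm.
    """
    bad = set(ratings["trial_type"].unique()) - {"signal", "noise"}
    if bad:
        raise CountTableError([f"unknown trial_type values: {sorted(bad)}"])
    counts = []
    for pid, grp in ratings.groupby("participant_id", sort=True):
        yes = grp.apply(
            lambda r: dichotomise(int(r["rating"]), int(r["scale_max"]), threshold),
            axis=1,
        )
        sig = grp["trial_type"] == "signal"
        counts.append(
            TrialCounts(
                participant_id=pid,
                h=int(yes[sig].sum()),
                f=int(yes[~sig].sum()),
                s=int(sig.sum()),
                n=int((~sig).sum()),
            )
        )
    return counts
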