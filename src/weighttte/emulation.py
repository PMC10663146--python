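"""Emulation strategies: time zero, exclusions and covariate sets.

Three strategies from the applied literature on weight-change exposures,
expressed as frozen :class:`MethodSpec` objects and two operations that
turn a simulated cohort into a method-specific person-period table for
discrete-time survival analysis:

* **method 1** — time zero at enrolment, no exclusions, adjustment for
  enrolment covariates only.  Its exposure indicators are populated from
  the weight change observed at the *end* of interval 1, so interval-1
  records condition on the future: that misalignment is the method's
  defining flaw, and it is reproduced here deliberately.
* **method 2** — time zero at the first follow-up visit; subjects with a
  first-interval event are excluded; adjustment for first-follow-up
  covariates (plus the fixed enrolment covariates); the clock is
  re-indexed so the modelled follow-up spans 18 years.
* **method 3** (the recommended strategy) — time zero at enrolment with
  interval 1 as a structural zero-risk baseline period; same exclusions
  as method 2; adjustment for covariates measured at *both* enrolment and
  first follow-up.

Methods 2 and 3 always act on the identical subject subset and identical
risk sets; they differ only in covariate set and in the time origin of
reported curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Cohort

__all__ = ["MethodSpec", "method_spec", "apply_exclusions", "expand_person_periods"]

METHOD_NAMES = ("method1", "method2", "method3")

_FIXED = ("age0", "sex", "famhist", "weight0")
_WAVE0 = ("smoking0", "diuretics0")
_WAVE1 = ("smoking1", "diuretics1")


@dataclass(frozen=True)
class MethodSpec:
    """Declarative description of one emulation strategy."""

    name: str
    time_zero: str  # "enrolment" | "first_followup"
    exclude_first_interval_cvd: bool
    exclude_first_interval_chronic: bool
    covariate_set: tuple[str, ...]
    first_modelled_interval: int  # on the enrolment clock (1-based)

    def modelled_intervals(self, n_intervals: int) -> range:
        """Modelled intervals on the enrolment clock."""
        return range(self.first_modelled_interval, n_intervals + 1)

    def clock_interval(self, enrolment_interval: np.ndarray) -> np.ndarray:
        """Map enrolment-clock interval indices onto the method's clock."""
        if self.time_zero == "first_followup":
            return enrolment_interval - 1
        return enrolment_interval

    def followup_years(self, n_intervals: int, interval_length: float) -> float:
        offset = 1 if self.time_zero == "first_followup" else 0
        return (n_intervals - offset) * interval_length


_SPECS = {
    "method1": MethodSpec(
        name="method1",
        time_zero="enrolment",
        exclude_first_interval_cvd=False,
        exclude_first_interval_chronic=False,
        covariate_set=_FIXED + _WAVE0,
        first_modelled_interval=1,
    ),
    "method2": MethodSpec(
        name="method2",
        time_zero="first_followup",
        exclude_first_interval_cvd=True,
        exclude_first_interval_chronic=False,
        covariate_set=_FIXED + _WAVE1,
        first_modelled_interval=2,
    ),
    "method3": MethodSpec(
        name="method3",
        time_zero="enrolment",
        exclude_first_interval_cvd=True,
        exclude_first_interval_chronic=False,
        covariate_set=_FIXED + _WAVE0 + _WAVE1,
        first_modelled_interval=2,
    ),
}

_ALIASES = {"1": "method1", "2": "method2", "3": "method3"}


def method_spec(name: str | int) -> MethodSpec:
    """Return the frozen spec for one of the three emulation methods."""
    key = _ALIASES.get(str(name), str(name))
    try:
        return _SPECS[key]
    except KeyError:
        raise ValueError(
            f"unknown method {name!r}; expected one of {METHOD_NAMES}"
        ) from None


def apply_exclusions(
    cohort: "Cohort", spec: MethodSpec, chronic_exclusion: bool | None = None
) -> tuple["Cohort", dict[str, int]]:
    """Apply the method's eligibility window to a cohort.

    Subjects with a CVD event in interval 1 are dropped when the spec says
    so; dropping subjects with first-interval chronic disease is available
    as an option (``chronic_exclusion=True``) for research questions that
    restrict to 'healthy' weight change.

    Returns the retained sub-cohort and a count of dropped subjects by
    reason (always reported, mirroring trial-profile bookkeeping).
    """
    from .simulate import Cohort  # local import to avoid a cycle

    df = cohort.subjects
    if chronic_exclusion is None:
        chronic_exclusion = spec.exclude_first_interval_chronic
    drop_cvd = np.zeros(len(df), dtype=bool)
    drop_chronic = np.zeros(len(df), dtype=bool)
    if spec.exclude_first_interval_cvd:
        drop_cvd = (df["event_interval"] == 1).fillna(False).to_numpy(dtype=bool)
    if chronic_exclusion:
        drop_chronic = df["chronic1"].to_numpy(dtype=bool) & ~drop_cvd
    kept = df.loc[~(drop_cvd | drop_chronic)].reset_index(drop=True)
    dropped = {
        "first_interval_cvd": int(drop_cvd.sum()),
        "first_interval_chronic": int(drop_chronic.sum()),
    }
    sub = Cohort(params=cohort.params, subjects=kept, seed_used=cohort.seed_used)
    return sub, dropped


def expand_person_periods(cohort: "Cohort", spec: MethodSpec) -> pd.DataFrame:
    """Expand a (post-exclusion) cohort into person-period records.

    One record per subject per at-risk modelled interval, up to and
    including the event interval, indexed on the method's clock.  Method 3
    starts modelling at enrolment-clock interval 2; its interval-1 baseline
    period is represented structurally in the survival curves rather than
    by degenerate all-zero outcome rows.

    Columns: ``id``, ``interval`` (method clock), ``event``,
    ``exposure_loss``, ``exposure_gain``, plus the spec's covariates.
    """
    params = cohort.params
    df = cohort.subjects
    n_int = params.n_intervals
    first = spec.first_modelled_interval

    ev = df["event_interval"].to_numpy(dtype=float)  # NaN = event-free
    ev = np.where(np.isnan(ev), np.inf, ev)
    if np.any(ev[np.isfinite(ev)] < first):
        raise ValueError(
            "cohort contains events before the first modelled interval; "
            "apply the method's exclusions first"
        )
    if np.any(ev[np.isfinite(ev)] > n_int):
        raise ValueError("event_interval outside 1..n_intervals")

    # number of at-risk modelled intervals per subject
    last = np.minimum(ev, n_int).astype(np.int64)
    counts = last - first + 1
    idx = np.repeat(np.arange(len(df)), counts)
    # enrolment-clock interval for every record
    offsets = np.concatenate([np.arange(c) for c in counts]) if len(df) else np.array([], dtype=np.int64)
    interval_enrol = first + offsets
    event = (interval_enrol == np.repeat(np.where(np.isinf(ev), -1, ev), counts)).astype(np.int64)

    cat = df["change_category"].to_numpy()
    out = pd.DataFrame(
        {
            "id": df["id"].to_numpy()[idx],
            "interval": spec.clock_interval(interval_enrol),
            "event": event,
            "exposure_loss": (cat == "loss").astype(np.int64)[idx],
            "exposure_gain": (cat == "gain").astype(np.int64)[idx],
        }
    )
    for name in spec.covariate_set:
        out[name] = df[name].to_numpy()[idx]
    return out
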