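"""Summary metrics of a dissolution/transport episode.

Definitions (all fractions are percentages of the initial particle mass):

* *dissolution fraction*: dissolved mass / initial mass;
* *deposition fraction*: mass absorbed by the epithelium / initial mass;
* *total deposition fraction*: the deposition fraction once the episode
  completes (everything is either on the epithelium or on the cilia);
* *complete dissolution time*: when the particle radius reaches zero;
* *complete deposition time*: first time the accounted mass
  (deposited + attached) reaches 99.9% of the initial mass;
* *maximum deposition time*: the time of peak *instantaneous* epithelial
  deposition rate.  (The cumulative fraction is monotone, so its literal
  maximum would always coincide with complete deposition; the rate peak is
  the quantity that distinguishes drugs.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = ["Metrics", "deposition_times", "fractions", "summarize"]

COMPLETION_THRESHOLD = 0.999


@dataclass
class Metrics:
    """Summary of one episode (times in s, fractions in %)."""

    total_deposition_fraction: float
    attached_fraction: float
    complete_deposition_time: float
    maximum_deposition_time: float
    complete_dissolution_time: float
    achieved_car: float
    layer_velocities: dict | None = None

    def as_dict(self) -> dict:
        out = {
            "total_deposition_fraction_pct": self.total_deposition_fraction,
            "attached_fraction_pct": self.attached_fraction,
            "complete_deposition_time_s": self.complete_deposition_time,
            "maximum_deposition_time_s": self.maximum_deposition_time,
            "complete_dissolution_time_s": self.complete_dissolution_time,
            "achieved_car": self.achieved_car,
        }
        if self.layer_velocities:
            out.update({f"mean_velocity_{k}_um_s": v
                        for k, v in self.layer_velocities.items()})
        return out


def deposition_times(t: np.ndarray, deposition_rate: np.ndarray,
                     accounted_fraction: np.ndarray,
                     threshold: float = COMPLETION_THRESHOLD):
    """(maximum deposition time, complete deposition time) from series.

    ``accounted_fraction`` is the monotone (deposited + attached) / m0
    ledger curve; ``deposition_rate`` the instantaneous epithelial
    absorption rate.  Returns NaN with a warning for the completion time if
    the threshold is never reached.
    """
    t = np.asarray(t, dtype=float)
    acc = np.asarray(accounted_fraction, dtype=float)
    if np.any(np.diff(acc) < -1e-12):
        raise ValueError("accounted-mass ledger must be non-decreasing")
    max_dep_time = float(t[int(np.argmax(deposition_rate))])
    hit = np.nonzero(acc >= threshold)[0]
    if hit.size == 0:
        warnings.warn("episode never reached the completion threshold; "
                      "complete deposition time is undefined", stacklevel=2)
        return max_dep_time, float("nan")
    return max_dep_time, float(t[hit[0]])


def fractions(ledgers: pd.DataFrame, initial_mass: float) -> pd.DataFrame:
    """Percentage curves from absolute-mass ledger columns.

    ``ledgers`` must hold columns ``t`` and any of ``dissolved``,
    ``deposited``, ``attached``, ``in_domain`` (kg).
    """
    if initial_mass <= 0:
        raise ValueError("initial mass must be positive")
    out = pd.DataFrame({"t": ledgers["t"]})
    for col in ("dissolved", "deposited", "attached", "in_domain"):
        if col in ledgers:
            out[f"{col}_pct"] = 100.0 * ledgers[col] / initial_mass
    return out


def summarize(result, layer_velocities: dict | None = None) -> Metrics:
    """Build a :class:`Metrics` from a transport episode result."""
    ts = result.timeseries
    acc = ts["deposition_fraction"] + ts["attached_fraction"]
    max_dep, complete_dep = deposition_times(
        ts["t"].to_numpy(), ts["deposition_rate"].to_numpy(), acc.to_numpy())
    return Metrics(
        total_deposition_fraction=100.0 * result.deposition_fraction,
        attached_fraction=100.0 * result.attached_fraction,
        complete_deposition_time=complete_dep,
        maximum_deposition_time=max_dep,
        complete_dissolution_time=result.t_dissolved,
        achieved_car=result.achieved_car,
        layer_velocities=layer_velocities)
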