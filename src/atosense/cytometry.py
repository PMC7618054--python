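"""Synthetic flow-cytometry dose-response studies.

Emulates the experimental workflow used to characterise the biosensors:
per-well single-cell GFP distributions (10,000 events/sample), rainbow-bead
calibration from instrument arbitrary units (a.u.) to molecules of
equivalent fluorophore (MEF), median summarisation per well, and >= 3
biological replicates per inducer concentration.  Single-cell fluorescence
is modelled as log-normal (strictly positive, right-skewed — the standard
choice for cytometry); biological replicate scatter is a multiplicative
log-normal factor on the true well median.

A "study" is generated from a Hill-shaped ground truth (a
:class:`~atosense.doseresponse.HillFit`-like fixture), so the whole
generate -> summarise -> fit pipeline can be exercised as a parameter
recovery experiment with no external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseCurve, HillFit, fit_hill, hill_eval

__all__ = [
    "EventSample",
    "BeadReference",
    "Calibration",
    "WellSummary",
    "Study",
    "FIXTURES",
    "DEFAULT_CONC_GRID",
    "IDENTITY_CALIBRATION",
    "generate_events",
    "generate_bead_reference",
    "fit_calibration",
    "summarize_well",
    "generate_study",
]

# Default acetoacetate grid (uM): 20 mM ceiling (the saturating concentration
# used for specificity controls) down through the sub-K1/2 regime, plus the
# uninduced well.
DEFAULT_CONC_GRID = np.array(
    [0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2500.0, 5000.0, 10000.0, 20000.0]
)

# Hill-shaped ground truths for recovery experiments.  K1/2 (uM) and, for
# asah0, the fold change (115, i.e. dynamic range 114) are the reported
# characterisations of the corresponding biosensor strains; the plateaus of
# the two plasmid-expression fixtures respect the qualitative ordering of
# the measured curves (higher basal, lower maximum than asah0; the low-copy
# variant lower in both), and n = 1.5 is a typical TCS response steepness.
FIXTURES: dict[str, HillFit] = {
    # BW25113 ASAH0: K1/2 = 344 uM, fold change 115
    "asah0": HillFit(fmin=100.0, fmax=11500.0, K=344.0, n=1.5),
    # BW28878 ASAH2J06: K1/2 = 31.7 uM
    "asah2j06": HillFit(fmin=300.0, fmax=6000.0, K=31.7, n=1.5),
    # BW28878 ASAL2J06 (low copy): K1/2 = 40.1 uM
    "asal2j06": HillFit(fmin=150.0, fmax=3000.0, K=40.1, n=1.5),
}


@dataclass(frozen=True)
class EventSample:
    """Per-event fluorescence of one well, arbitrary units."""

    values: np.ndarray
    well_id: str
    inducer_conc: float
    replicate: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values <= 0):
            raise ValueError("event fluorescence must be > 0 (log-normal support)")


@dataclass(frozen=True)
class BeadReference:
    """Known-MEF rainbow bead peaks and their observed a.u. positions."""

    peak_au: np.ndarray
    peak_mef: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "peak_au", np.asarray(self.peak_au, dtype=float))
        object.__setattr__(self, "peak_mef", np.asarray(self.peak_mef, dtype=float))
        if len(self.peak_au) != len(self.peak_mef) or len(self.peak_au) < 4:
            raise ValueError("need >= 4 matched bead peaks")
        for arr, nm in ((self.peak_au, "peak_au"), (self.peak_mef, "peak_mef")):
            if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{nm} must be strictly increasing and positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"peak_au": self.peak_au, "peak_mef": self.peak_mef}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BeadReference":
        df = pd.read_csv(path)
        return cls(df["peak_au"].to_numpy(), df["peak_mef"].to_numpy())


@dataclass(frozen=True)
class Calibration:
    """log10(MEF) = intercept + slope * log10(a.u.)"""

    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0 (monotone map)")

    def au_to_mef(self, au):
        return 10.0 ** (self.intercept + self.slope * np.log10(au))


IDENTITY_CALIBRATION = Calibration(slope=1.0, intercept=0.0, r_squared=1.0)


@dataclass(frozen=True)
class WellSummary:
    """Median fluorescence of one well, raw and calibrated."""

    inducer_conc: float
    replicate: int
    median_au: float
    median_mef: float
    well_id: str = ""


def generate_events(
    median_au: float,
    cv: float,
    n_events: int = 10_000,
    seed=None,
    well_id: str = "",
    inducer_conc: float = 0.0,
    replicate: int = 0,
) -> EventSample:
    """Log-normal single-cell sample with the requested median and CV.

    The log-median is log(median_au) (the median of a log-normal is exp(mu))
    and the log-sd is sqrt(log(1 + cv^2)), which fixes the coefficient of
    variation of the linear-scale distribution at ``cv``.
    """
    if median_au <= 0:
        raise ValueError("median_au must be > 0")
    if not 0 < cv < 2:
        raise ValueError("cv must be in (0, 2)")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    values = rng.lognormal(mean=math.log(median_au), sigma=sigma, size=int(n_events))
    return EventSample(values, well_id=well_id, inducer_conc=inducer_conc, replicate=replicate)


def generate_bead_reference(
    n_peaks: int = 8,
    gain: float = 0.5,
    noise: float = 0.0,
    seed=None,
) -> BeadReference:
    """Synthetic rainbow-bead ladder: decade-ish spaced MEF peaks observed
    at a.u. = gain * MEF, optionally with multiplicative log-normal noise."""
    mef = np.logspace(2, 2 + 0.7 * (n_peaks - 1), n_peaks)
    au = gain * mef
    if noise > 0:
        rng = np.random.default_rng(seed)
        au = au * rng.lognormal(0.0, noise, size=n_peaks)
        au = np.sort(au)
    return BeadReference(peak_au=au, peak_mef=mef)


def fit_calibration(beads: BeadReference) -> Calibration:
    """OLS of log10(MEF) on log10(a.u.) over the bead peaks."""
    x = np.log10(beads.peak_au)
    y = np.log10(beads.peak_mef)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Calibration(slope=float(slope), intercept=float(intercept), r_squared=r2)


def summarize_well(events: EventSample, cal: Calibration = IDENTITY_CALIBRATION) -> WellSummary:
    """Median a.u. of the well plus its MEF transform.

    The calibration is monotone, so transforming the median equals the
    median of the transformed events.
    """
    med = float(np.median(events.values))
    return WellSummary(
        inducer_conc=events.inducer_conc,
        replicate=events.replicate,
        median_au=med,
        median_mef=float(cal.au_to_mef(med)),
        well_id=events.well_id,
    )


@dataclass(frozen=True)
class Study:
    """One synthetic dose-response study: raw events plus well medians."""

    wells: list
    events: list
    calibration: Calibration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(w) for w in self.wells])

    def events_frame(self) -> pd.DataFrame:
        frames = []
        for ev in self.events:
            frames.append(pd.DataFrame({
                "well_id": ev.well_id,
                "inducer_conc": ev.inducer_conc,
                "replicate": ev.replicate,
                "value": ev.values,
            }))
        return pd.concat(frames, ignore_index=True)

    def to_curve(self, use_mef: bool = True) -> DoseResponseCurve:
        """Collapse replicates: mean of the replicate medians per dose,
        with the replicate SD carried as the dispersion."""
        df = self.to_frame()
        col = "median_mef" if use_mef else "median_au"
        g = df.groupby("inducer_conc")[col]
        mean = g.mean().sort_index()
        sd = g.std(ddof=1).sort_index().to_numpy()
        sd_arg = sd if np.all(np.isfinite(sd)) else None
        return DoseResponseCurve(mean.index.to_numpy(), mean.to_numpy(), sd_arg)

    def fit(self, use_mef: bool = True, n_fixed=None) -> HillFit:
        return fit_hill(self.to_curve(use_mef=use_mef), n_fixed=n_fixed)


def generate_study(
    fixture: HillFit,
    conc_grid=None,
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed=None,
    event_cv: float = 0.4,
    n_events: int = 10_000,
    calibration: Calibration = IDENTITY_CALIBRATION,
) -> Study:
    """Generate a full synthetic dose-response study from a Hill truth.

    Per (concentration, replicate) well the true median is
    ``hill_eval(conc, fixture)`` times a log-normal replicate factor with
    coefficient of variation ``noise_cv`` (median-preserving: the factor has
    log-mean 0).  Events are then drawn log-normally around that median with
    single-cell spread ``event_cv`` (``event_cv -> 0`` gives an effectively
    noise-free well median).  Everything is reproducible from ``seed``.
    """
    grid = DEFAULT_CONC_GRID if conc_grid is None else np.asarray(conc_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid must be non-empty")
    if replicates < 3:
        raise ValueError("need >= 3 biological replicates")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma_rep = math.sqrt(math.log1p(noise_cv * noise_cv)) if noise_cv > 0 else 0.0
    wells, events = [], []
    for conc in grid:
        for rep in range(1, replicates + 1):
            true_median = hill_eval(float(conc), fixture.fmin, fixture.fmax, fixture.K, fixture.n)
            if sigma_rep > 0:
                true_median *= float(rng.lognormal(0.0, sigma_rep))
            ev = generate_events(
                true_median,
                cv=max(event_cv, 1e-9),
                n_events=n_events,
                seed=rng.integers(0, 2**31 - 1),
                well_id=f"c{conc:g}_r{rep}",
                inducer_conc=float(conc),
                replicate=rep,
            )
            events.append(ev)
            wells.append(summarize_well(ev, calibration))
    return Study(wells=wells, events=events, calibration=calibration)


def load_fixture(path) -> HillFit:
    """Read a Hill-shaped truth from a JSON file (fmin, fmax, K, n)."""
    with open(path) as fh:
        d = json.load(fh)
    return HillFit(fmin=d["fmin"], fmax=d["fmax"], K=d["K"], n=d["n"])
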