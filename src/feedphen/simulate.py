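"""Synthetic automatic-feeder herd generator.

Emulates the data stream of an electronic feeding station: visit-level feed
intake (g), occupation time (s), and platform body weight (kg), for a herd
of growing boars.  Each animal follows a three-parameter logistic growth
curve; daily feed is the animal's feed conversion ratio times its daily
gain plus day-level noise, split across a Poisson number of visits.  A
configurable fraction of visits is replaced by anomalies drawn strictly
inside the violating region of one of the eight visit-level QC rules; the
clean values are kept in the returned anomaly table so downstream
imputation accuracy can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ANOMALY_CLASSES, SimConfig

EVENT_COLUMNS = ["pig_id", "day", "visit", "otv_s", "fiv_g", "bw_kg"]
TRUTH_COLUMNS = [
    "pig_id", "bw_entry", "bw_max", "xmid", "scal",
    "true_adg", "true_fcr", "linear_slope",
]

# Hard per-visit intake cap (g); with the occupation-time cap below it keeps
# every clean visit inside all eight QC rules by construction.
_FIV_CAP_G = 1800.0
_OTV_CAP_MIN = 55.0  # minutes; feeder rules reject occupations over 60 min
_VISIT_SHAPE = 4.0  # gamma shape for within-day intake shares


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated animal."""

    pig_id: int
    bw_entry: float
    bw_max: float
    xmid: float  # days since test entry at which BW = bw_max / 2
    scal: float  # days
    true_adg: float  # kg/day averaged over the 30-120 kg range
    true_fcr: float  # kg feed per kg gain
    linear_slope: float  # kg/day: OLS slope of the noise-free trajectory

    def bw_at(self, day):
        day = np.asarray(day, dtype=float)
        return self.bw_max / (1.0 + np.exp((self.xmid - day) / self.scal))

    def day_at(self, weight):
        """Fractional day since entry at which the noise-free curve crosses
        ``weight`` kg (weight must be below ``bw_max``)."""
        weight = np.asarray(weight, dtype=float)
        if np.any(weight >= self.bw_max) or np.any(weight <= 0):
            raise ValueError("weight outside (0, bw_max)")
        return self.xmid - self.scal * np.log(self.bw_max / weight - 1.0)

    def true_cfi_at(self, weight):
        """Noise-free cumulative feed intake (kg) accumulated from test
        entry until the animal reaches ``weight`` kg."""
        weight = np.asarray(weight, dtype=float)
        return self.true_fcr * np.clip(weight - self.bw_entry, 0.0, None)

    @classmethod
    def from_row(cls, row) -> "SimTruth":
        return cls(**{k: row[k] for k in TRUTH_COLUMNS})


@dataclass
class SimResult:
    """Simulator output: the visit table, per-animal truth, and the ledger
    of injected anomalies (event row label, class, clean values)."""

    events: pd.DataFrame
    truth: pd.DataFrame
    anomalies: pd.DataFrame

    def truth_for(self, pig_id: int) -> SimTruth:
        row = self.truth.loc[self.truth["pig_id"] == pig_id]
        if row.empty:
            raise KeyError(f"unknown pig_id {pig_id}")
        return SimTruth.from_row(row.iloc[0])


def _truncated_normal(rng, mean, sd, size, lower=None, upper=None):
    """Gaussian draws resampled (not clipped) into (lower, upper)."""
    out = rng.normal(mean, sd, size)
    if sd == 0:
        return out
    for _ in range(1000):
        bad = np.zeros(size, dtype=bool)
        if lower is not None:
            bad |= out <= lower
        if upper is not None:
            bad |= out >= upper
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("truncated normal failed to converge; check bounds")


def _solve_scal(bw_max: np.ndarray, adg: np.ndarray) -> np.ndarray:
    """Steepness such that the 30->120 kg average daily gain equals ``adg``.

    Days from 30 to 120 kg on the logistic curve are
    ``scal * [ln(bw_max/30 - 1) - ln(bw_max/120 - 1)]``; setting that travel
    time to ``90 / adg`` and solving for scal.
    """
    span = np.log(bw_max / 30.0 - 1.0) - np.log(bw_max / 120.0 - 1.0)
    return 90.0 / (adg * span)


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate a herd of feeder-visit records with ground truth.

    Returns a :class:`SimResult`.  With all anomaly rates at zero the event
    table passes every visit-level QC rule by construction, and per animal
    and day the visit intakes sum exactly to the drawn daily feed.
    """
    rng = np.random.default_rng(config.seed)
    n, days = config.n_pigs, config.days

    # ---- per-animal parameters -------------------------------------------
    bw0 = _truncated_normal(rng, config.bw_entry_mean, config.bw_entry_sd, n,
                            lower=5.0)
    bw_max = _truncated_normal(rng, config.bw_max_mean, config.bw_max_sd, n,
                               lower=config.bw_max_min)
    adg = _truncated_normal(rng, config.adg_mean, config.adg_sd, n, lower=0.3)
    fcr = _truncated_normal(rng, config.fcr_mean, config.fcr_sd, n, lower=1.0)
    rate = _truncated_normal(rng, config.feed_rate_mean, config.feed_rate_sd,
                             n, lower=config.feed_rate_min,
                             upper=config.feed_rate_max)
    scal = _solve_scal(bw_max, adg)
    xmid = scal * np.log(bw_max / bw0 - 1.0)

    # ---- noise-free daily trajectories (n, days) -------------------------
    day_grid = np.arange(days, dtype=float)
    bw_clean = bw_max[:, None] / (
        1.0 + np.exp((xmid[:, None] - day_grid[None, :]) / scal[:, None]))
    # gain during day d moves the animal from bw_clean[d] to bw_clean[d+1]
    bw_next = bw_max[:, None] / (
        1.0 + np.exp((xmid[:, None] - (day_grid[None, :] + 1.0)) / scal[:, None]))
    gain = bw_next - bw_clean

    # weight-dependent noise profile (1.0 everywhere by default)
    taper = max(config.noise_taper_bw, 30.0 + 1e-9)
    frac = np.clip((bw_clean - 30.0) / (taper - 30.0), 0.0, 1.0)
    noise_factor = config.early_noise_scale + (1.0 - config.early_noise_scale) * frac

    feed = fcr[:, None] * gain
    if config.dfi_noise_sd > 0:
        sd_grid = config.dfi_noise_sd * noise_factor
        feed_noisy = feed + rng.normal(0.0, 1.0, feed.shape) * sd_grid
        for _ in range(1000):
            bad = feed_noisy <= 0.01
            if not bad.any():
                break
            feed_noisy[bad] = feed[bad] + rng.normal(
                0.0, 1.0, int(bad.sum())) * sd_grid[bad]
        feed = np.clip(feed_noisy, 0.01, None)

    if config.bw_noise_sd > 0:
        bw_obs = bw_clean + rng.normal(0.0, 1.0, bw_clean.shape) \
            * config.bw_noise_sd * noise_factor
    else:
        bw_obs = bw_clean.copy()
    np.clip(bw_obs, 1.0, None, out=bw_obs)

    # OLS slope of the noise-free daily BW: the estimand of the per-animal
    # linear growth fit (differs from 30-120 kg ADG because growth is
    # sigmoidal over the observed span).
    dc = day_grid - day_grid.mean()
    linear_slope = (bw_clean * dc).sum(axis=1) / (dc ** 2).sum()

    # ---- visit structure -------------------------------------------------
    feed_g = feed * 1000.0
    cap = np.minimum(_FIV_CAP_G, rate * _OTV_CAP_MIN)  # per-visit intake cap
    k = rng.poisson(config.visits_per_day_mean, size=(n, days))
    k_min = np.ceil(feed_g / (0.8 * cap[:, None])).astype(int)
    k = np.maximum(np.maximum(k, 2), k_min)

    k_flat = k.ravel()
    n_events = int(k_flat.sum())
    seg = np.repeat(np.arange(n * days), k_flat)

    shares = rng.gamma(_VISIT_SHAPE, 1.0, n_events)
    seg_sum = np.bincount(seg, weights=shares, minlength=n * days)
    shares /= seg_sum[seg]
    fiv = feed_g.ravel()[seg] * shares

    # days where the gamma split breached the cap fall back to equal shares,
    # which always respects it because k >= feed / (0.8 * cap)
    cap_flat = np.repeat(cap, days)[seg]
    over = np.bincount(seg, weights=(fiv > cap_flat), minlength=n * days) > 0
    if over.any():
        equal = over[seg]
        fiv[equal] = feed_g.ravel()[seg][equal] / k_flat[seg][equal]

    pig_ids = np.arange(1, n + 1)
    pig_of_event = np.repeat(np.repeat(pig_ids, days), k_flat)
    day_of_event = np.repeat(np.tile(np.arange(days), n), k_flat)
    starts = np.concatenate(([0], np.cumsum(k_flat)[:-1]))
    visit_idx = np.arange(n_events) - np.repeat(starts, k_flat) + 1

    rate_of_event = np.repeat(rate, days)[seg]
    otv = fiv / rate_of_event * 60.0
    bw_visit = bw_obs.ravel()[seg]
    if config.bw_visit_jitter_sd > 0:
        bw_visit = bw_visit + rng.normal(0.0, config.bw_visit_jitter_sd,
                                         n_events)
        bw_visit = np.clip(bw_visit, 0.5, None)

    events = pd.DataFrame({
        "pig_id": pig_of_event.astype(np.int64),
        "day": day_of_event.astype(np.int64),
        "visit": visit_idx.astype(np.int64),
        "otv_s": otv,
        "fiv_g": fiv,
        "bw_kg": bw_visit,
    })

    anomalies = _inject_anomalies(rng, events, config)

    truth = pd.DataFrame({
        "pig_id": pig_ids.astype(np.int64),
        "bw_entry": bw0,
        "bw_max": bw_max,
        "xmid": xmid,
        "scal": scal,
        "true_adg": adg,
        "true_fcr": fcr,
        "linear_slope": linear_slope,
    })
    return SimResult(events=events, truth=truth, anomalies=anomalies)


def contaminate_weights(daily: pd.DataFrame, fraction: float, rng,
                        displacement: float = 40.0,
                        mean_run_length: float = 3.0) -> pd.DataFrame:
    """Displace ~``fraction`` of each animal's daily weights upward.

    Contaminated days come in short consecutive runs (geometric length,
    mean ``mean_run_length``), emulating the persistent artifacts feeder
    stations produce — a second animal standing on the platform or a
    misread ear tag lasting several days — rather than isolated spikes.
    Returns a copy with the ``bw_kg`` column modified.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = daily.copy()
    bw = out["bw_kg"].to_numpy(dtype=float).copy()
    for _, pos in out.groupby("pig_id", sort=True).indices.items():
        n = len(pos)
        target = max(1, round(n * fraction)) if fraction > 0 else 0
        hit: set[int] = set()
        while len(hit) < target:
            start = int(rng.integers(0, n))
            length = int(rng.geometric(1.0 / mean_run_length))
            hit.update(range(start, min(n, start + length)))
        bw[pos[sorted(hit)[:target]]] += displacement
    out["bw_kg"] = bw
    return out


def _inject_anomalies(rng, events: pd.DataFrame,
                      config: SimConfig) -> pd.DataFrame:
    """Overwrite a random subset of visits with values sampled uniformly
    inside the violating region of one QC rule each; record clean values."""
    n_events = len(events)
    rates = [config.anomaly_rates.get(c, 0.0) for c in ANOMALY_CLASSES]
    edges = np.concatenate(([0.0], np.cumsum(rates),
                            [np.cumsum(rates)[-1] + config.missing_rate]))
    u = rng.random(n_events)
    # class index 1..8, 9 = missing-field record, 0 = untouched
    cls = np.searchsorted(edges[1:], u, side="right") + 1
    cls[u >= edges[-1]] = 0

    rows, classes, clean_fiv, clean_otv = [], [], [], []
    fiv = events["fiv_g"].to_numpy().copy()
    otv = events["otv_s"].to_numpy().copy()
    bw = events["bw_kg"].to_numpy().copy()

    for c in range(1, 10):
        idx = np.flatnonzero(cls == c)
        if idx.size == 0:
            continue
        m = idx.size
        rows.extend(events.index[idx])
        classes.extend([c] * m)
        clean_fiv.extend(fiv[idx])
        clean_otv.extend(otv[idx])
        if c == 1:  # negative intake
            fiv[idx] = rng.uniform(-500.0, -0.5, m)
        elif c == 2:  # implausibly large intake
            fiv[idx] = rng.uniform(2001.0, 5000.0, m)
        elif c == 3:  # intake recorded with zero occupation time
            otv[idx] = 0.0
            fiv[idx] = rng.uniform(25.0, 1800.0, m)
        elif c == 4:  # negative occupation time
            otv[idx] = rng.uniform(-600.0, -1.0, m)
        elif c == 5:  # occupation over an hour
            otv[idx] = rng.uniform(3601.0, 7200.0, m)
        elif c == 6:  # small intake at an impossible rate
            fiv[idx] = rng.uniform(5.0, 45.0, m)
            otv[idx] = fiv[idx] * 60.0 / rng.uniform(550.0, 900.0, m)
        elif c == 7:  # large intake at an impossible rate
            fiv[idx] = rng.uniform(60.0, 1500.0, m)
            otv[idx] = fiv[idx] * 60.0 / rng.uniform(360.0, 600.0, m)
        elif c == 8:  # long occupation with no feed dispensed
            fiv[idx] = 0.0
            otv[idx] = rng.uniform(501.0, 3600.0, m)
        elif c == 9:  # incomplete record
            which = rng.integers(0, 3, m)
            fiv[idx[which == 0]] = np.nan
            otv[idx[which == 1]] = np.nan
            bw[idx[which == 2]] = np.nan

    events["fiv_g"] = fiv
    events["otv_s"] = otv
    events["bw_kg"] = bw
    return pd.DataFrame({
        "event_row": np.asarray(rows, dtype=np.int64),
        "anomaly_class": np.asarray(classes, dtype=np.int64),
        "clean_fiv_g": np.asarray(clean_fiv, dtype=float),
        "clean_otv_s": np.asarray(clean_otv, dtype=float),
    })
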