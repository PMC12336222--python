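"""HRV/RRV feature bank: 232 named features per 30-s epoch.

Families (name prefixes ``JJ_``/``BB_``/``HR_``, window infix ``{1,2,5,10}min``):

* time domain (34): Mean/Median/Max/Min/MAD, RMSSD/SDNN/SDSD/CVNN/CVSD/RMSA,
  NN20/PNN20/NN50/PNN50 (JJ), HR stats (from 60/JJ), TINN/HTI;
* frequency domain (44): band powers LF/HF/MF/VL/TF/TLF/ULF/Ttlpwr, band peak
  frequencies, normalized powers, ratios, HFmaxf/HFamp — on a 4 Hz
  cubic-resampled tachogram with a Welch PSD;
* Poincare geometry (14): SD1/SD2/SD1SD2/S/CVI/CSI/CSI_Modified;
* heart-rate asymmetry (14, JJ only): Guzik index and the
  deceleration/acceleration decomposition of SD1/SD2/SDNN;
* complexity (2): sample entropy (m=2, r=0.2*SD);
* multi-scale windows (124): time-domain statistics over the current epoch
  concatenated with the following 1/3/9/19 epochs (1/2/5/10-min windows),
  plus SDANN/SDNNI from per-minute segmentation.

Features that cannot be evaluated on an epoch (too few intervals, empty
band) are NaN and are median-imputed at table assembly; the imputation
mask is preserved.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.signal import welch

from .signals import EpochIntervals

HIST_BIN = 1.0 / 128.0  # s, histogram bin width for TINN/HTI/Mode

#: Frequency band table (Hz). TLF ("total low frequency") spans ULF+VLF;
#: TF is the conventional total band. Edges are configurable at call sites.
BANDS: dict[str, tuple[float, float]] = {
    "ULF": (0.0, 0.0033),
    "VL": (0.0033, 0.04),
    "LF": (0.04, 0.15),
    "MF": (0.08, 0.15),
    "HF": (0.15, 0.40),
    "TLF": (0.0, 0.04),
    "TF": (0.0, 0.40),
}

WINDOW_MINUTES = (1, 2, 5, 10)
#: epochs appended to the current one for each window length
WINDOW_EXTRA = {1: 1, 2: 3, 5: 9, 10: 19}


# ---------------------------------------------------------------- registry

@dataclass(frozen=True)
class RegistryEntry:
    name: str
    family: str
    source: str  # JJ | BB | HR
    window: str  # 30s | 1min | 2min | 5min | 10min


def build_registry() -> list[RegistryEntry]:
    """The fixed, ordered 232-feature registry."""
    ent: list[RegistryEntry] = []

    def add(names, family, source, window="30s", prefix=None):
        p = prefix if prefix is not None else source
        for n in names:
            ent.append(RegistryEntry(f"{p}_{n}", family, source, window))

    basic = ["Mean", "Median", "Max", "Min", "MAD"]
    spread = ["RMSSD", "SDNN", "SDSD", "CVNN", "CVSD", "RMSA"]
    for src in ("JJ", "BB"):
        add(basic, "time", src)
    for src in ("JJ", "BB"):
        add(spread, "time", src)
    add(["NN20", "PNN20", "NN50", "PNN50"], "time", "JJ")
    add(["Mean", "Min", "Max", "Std"], "time", "JJ", prefix="HR")
    for src in ("JJ", "BB"):
        add(["TINN", "HTI"], "time", src)

    freq_groups = [
        ["LF", "HF", "MF", "VL", "TF", "TLF", "ULF", "Ttlpwr"],
        ["LFf", "HFf", "MFf", "TLFf", "TFf"],
        ["LFn", "HFn", "MFn", "TLFn"],
        ["LFHF", "MFLF", "TLFLF"],
        ["HFmaxf", "HFamp"],
    ]
    for grp in freq_groups:
        for src in ("JJ", "BB"):
            add(grp, "frequency", src)

    for grp in [["SD1", "SD2", "SD1SD2", "S"], ["CVI", "CSI", "CSI_Modified"]]:
        for src in ("JJ", "BB"):
            add(grp, "poincare", src)

    add(
        ["GI", "C1d", "C1a", "SD1d", "SD1a", "C2d", "C2a", "SD2d", "SD2a",
         "SD2I", "Cd", "Ca", "SDNNd", "SDNNa"],
        "asymmetry", "JJ",
    )

    for src in ("JJ", "BB"):
        add(["SampEn"], "complexity", src)

    win_basic = ["Mean", "Median", "Mode", "Max", "Min", "MAD"]
    win_spread = ["RMSSD", "SDNN", "SDSD", "CVNN", "CVSD", "SDANN", "SDNNI"]
    for names, srcs in ((win_basic, ("JJ", "BB")), (win_spread, ("JJ", "BB"))):
        for w in WINDOW_MINUTES:
            for src in srcs:
                for n in names:
                    ent.append(
                        RegistryEntry(f"{src}_{w}min_{n}", "multiscale", src, f"{w}min")
                    )
    for w in WINDOW_MINUTES:
        ent.append(RegistryEntry(f"JJ_{w}min_PNN50", "multiscale", "JJ", f"{w}min"))
    for w in WINDOW_MINUTES:
        for n in ["Mean", "Min", "Max", "Std"]:
            ent.append(RegistryEntry(f"HR_{w}min_{n}", "multiscale", "HR", f"{w}min"))
    return ent


REGISTRY = build_registry()
REGISTRY_NAMES = [e.name for e in REGISTRY]


def registry_checksum() -> str:
    """SHA-256 over the ordered registry names; guards against silent drift."""
    return hashlib.sha256("\n".join(REGISTRY_NAMES).encode()).hexdigest()


def family_counts() -> dict[str, int]:
    out: dict[str, int] = {}
    for e in REGISTRY:
        out[e.family] = out.get(e.family, 0) + 1
    return out


# ----------------------------------------------------------- time domain

def _mad(v: np.ndarray) -> float:
    return float(np.median(np.abs(v - np.median(v))))


def _hist(v: np.ndarray):
    lo = np.floor(v.min() / HIST_BIN) * HIST_BIN
    nbins = max(1, int(np.ceil((v.max() - lo) / HIST_BIN + 1e-9)))
    counts, edges = np.histogram(v, bins=nbins, range=(lo, lo + nbins * HIST_BIN))
    return counts, edges


def triangular_index(v: np.ndarray) -> tuple[float, float]:
    """(TINN, HTI) from the 1/128-s-bin interval histogram.

    TINN is the base width M-N of the least-squares triangular fit through
    the histogram peak; left and right base points are optimized
    independently (the two sides of the triangle are separable in the
    squared error).  HTI is total count / modal count.
    """
    counts, edges = _hist(v)
    centers = (edges[:-1] + edges[1:]) / 2
    peak = int(np.argmax(counts))
    hti = float(len(v) / counts[peak])
    if len(counts) == 1:
        return 0.0, hti

    def _side(idx_range, direction):
        # choose base point minimizing sum (D - triangle)^2 on that side
        best_err, best_pos = None, centers[peak]
        for b in idx_range:
            x0, x1 = centers[b], centers[peak]
            tri = counts[peak] * (centers - x0) / (x1 - x0) if x1 != x0 else None
            if tri is None:
                continue
            lo, hi = (b, peak) if direction < 0 else (peak, b)
            seg = slice(min(lo, hi), max(lo, hi) + 1)
            pred = np.clip(tri[seg], 0, None) if direction < 0 else np.clip(
                counts[peak] * (centers[seg] - x0) / (x1 - x0), 0, None
            )
            err = float(np.sum((counts[seg] - pred) ** 2))
            # bins outside [base, peak] on this side must be ~0 in the fit
            outside = slice(0, min(lo, hi)) if direction < 0 else slice(max(lo, hi) + 1, len(counts))
            err += float(np.sum(counts[outside] ** 2))
            if best_err is None or err < best_err - 1e-12:
                best_err, best_pos = err, centers[b]
        return best_pos

    n_pos = _side(range(0, peak), -1) if peak > 0 else centers[0] - HIST_BIN
    m_pos = _side(range(peak + 1, len(counts)), +1) if peak < len(counts) - 1 else centers[-1] + HIST_BIN
    return float(m_pos - n_pos), hti


def time_domain(values: np.ndarray, source: str = "JJ") -> dict[str, float]:
    """Standard 30-s time-domain statistics; NaN when fewer than 2 values."""
    v = np.asarray(values, dtype=float)
    names = ["Mean", "Median", "Max", "Min", "MAD", "RMSSD", "SDNN", "SDSD",
             "CVNN", "CVSD", "RMSA", "TINN", "HTI"]
    if source == "JJ":
        names += ["NN20", "PNN20", "NN50", "PNN50",
                  "HR_Mean", "HR_Min", "HR_Max", "HR_Std"]
    if v.size < 2:
        return {n: np.nan for n in names}
    d = np.diff(v)
    mean = float(v.mean())
    sdnn = float(v.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(d**2)))
    out = {
        "Mean": mean,
        "Median": float(np.median(v)),
        "Max": float(v.max()),
        "Min": float(v.min()),
        "MAD": _mad(v),
        "RMSSD": rmssd,
        "SDNN": sdnn,
        "SDSD": float(d.std(ddof=1)) if d.size > 1 else np.nan,
        "CVNN": sdnn / mean if mean != 0 else np.nan,
        "CVSD": rmssd / mean if mean != 0 else np.nan,
        "RMSA": float(np.sqrt(np.mean(v**2))),
    }
    out["TINN"], out["HTI"] = triangular_index(v)
    if source == "JJ":
        ad = np.abs(d)
        out["NN20"] = float(np.sum(ad > 0.020))
        out["PNN20"] = out["NN20"] / d.size
        out["NN50"] = float(np.sum(ad > 0.050))
        out["PNN50"] = out["NN50"] / d.size
        hr = 60.0 / v
        out["HR_Mean"] = float(hr.mean())
        out["HR_Min"] = float(hr.min())
        out["HR_Max"] = float(hr.max())
        out["HR_Std"] = float(hr.std(ddof=1))
    return out


# ------------------------------------------------------- frequency domain

def tachogram_psd(values: np.ndarray, resample_hz: float = 4.0):
    """Welch PSD of the cubic-resampled interval tachogram.

    Interval i is located at the time of its later peak (cumulative sum of
    the interval series); the tachogram is resampled at ``resample_hz``.
    """
    v = np.asarray(values, dtype=float)
    t = np.cumsum(v)
    if v.size < 4:
        raise ValueError("need >= 4 intervals for a spectrum")
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    rr = interp1d(t, v, kind="cubic")(grid)
    rr = rr - rr.mean()
    nperseg = min(256, len(rr))
    f, pxx = welch(rr, fs=resample_hz, nperseg=nperseg)
    return f, pxx


def _band_power(f, pxx, lo, hi) -> float:
    sel = (f >= lo) & (f <= hi)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[sel], f[sel]))


def frequency_domain(
    values: np.ndarray,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Band powers, peak frequencies, normalized powers and ratios."""
    bands = bands or BANDS
    names = (list(bands) + ["Ttlpwr"]
             + ["LFf", "HFf", "MFf", "TLFf", "TFf"]
             + ["LFn", "HFn", "MFn", "TLFn"]
             + ["LFHF", "MFLF", "TLFLF", "HFmaxf", "HFamp"])
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        return {n: np.nan for n in names}
    duration = float(v.sum())
    f, pxx = tachogram_psd(v)
    out: dict[str, float] = {}
    for b, (lo, hi) in bands.items():
        # a band is resolvable only if the window holds one full cycle of it
        need = 1.0 / lo if lo > 0 else 1.0 / hi
        out[b] = _band_power(f, pxx, lo, hi) if duration >= need else np.nan
    out["Ttlpwr"] = float(np.trapezoid(pxx, f))
    # below this power, a band is numerically empty: its peak frequency,
    # normalized share and ratios are meaningless and flagged missing
    POWER_EPS = 1e-15
    for b in ("LF", "HF", "MF", "TLF", "TF"):
        lo, hi = bands[b]
        sel = (f >= lo) & (f <= hi)
        resolvable = sel.any() and not np.isnan(out[b]) and out[b] > POWER_EPS
        out[b + "f"] = float(f[sel][np.argmax(pxx[sel])]) if resolvable else np.nan
    denom = out["TF"] - np.nan_to_num(out["VL"]) - np.nan_to_num(out["ULF"])
    for b in ("LF", "HF", "MF", "TLF"):
        out[b + "n"] = out[b] / denom if denom > POWER_EPS else np.nan
    def _ratio(num, den):
        return num / den if den > POWER_EPS and not np.isnan(num) else np.nan
    out["LFHF"] = _ratio(out["LF"], out["HF"])
    out["MFLF"] = _ratio(out["MF"], out["LF"])
    out["TLFLF"] = _ratio(out["TLF"], out["LF"])
    lo, hi = bands["HF"]
    sel = (f >= lo) & (f <= hi)
    if sel.any() and out["HF"] > POWER_EPS:
        k = np.argmax(pxx[sel])
        out["HFmaxf"] = float(f[sel][k])
        out["HFamp"] = float(pxx[sel][k])
    else:
        out["HFmaxf"] = out["HFamp"] = np.nan
    return out


# ------------------------------------------------------ Poincare geometry

def poincare(values: np.ndarray) -> dict[str, float]:
    """Ellipse descriptors of the lag-1 Poincare plot."""
    names = ["SD1", "SD2", "SD1SD2", "S", "CVI", "CSI", "CSI_Modified"]
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return {n: np.nan for n in names}
    var = float(v.var(ddof=1))
    vard = float(np.diff(v).var(ddof=1))
    sd1 = float(np.sqrt(vard / 2))
    sd2sq = 2 * var - vard / 2
    sd2 = float(np.sqrt(max(sd2sq, 0.0)))
    out = {"SD1": sd1, "SD2": sd2, "S": float(np.pi * sd1 * sd2)}
    if sd1 > 1e-12 and sd2 > 1e-12:  # ratio features undefined at zero spread
        out["SD1SD2"] = sd1 / sd2
        out["CSI"] = sd2 / sd1
        out["CVI"] = float(np.log10(16 * sd1 * sd2))
        out["CSI_Modified"] = 4 * sd2**2 / sd1
    else:
        out.update({"SD1SD2": np.nan, "CSI": np.nan, "CVI": np.nan,
                    "CSI_Modified": np.nan})
    return out


def asymmetry(values: np.ndarray) -> dict[str, float]:
    """Heart-rate-asymmetry decomposition of the Poincare plot.

    Signed distance to the identity line d_i = (x_{i+1}-x_i)/sqrt(2)
    partitions points into decelerations (d>0) and accelerations (d<0);
    along-line spread is measured from the centroid.  Points on the line
    contribute to neither side, so C1d+C1a = 1 and Cd+Ca = 1 exactly.
    """
    names = ["GI", "C1d", "C1a", "SD1d", "SD1a", "C2d", "C2a", "SD2d",
             "SD2a", "SD2I", "Cd", "Ca", "SDNNd", "SDNNa"]
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return {n: np.nan for n in names}
    x, y = v[:-1], v[1:]
    d = (y - x) / np.sqrt(2)
    M = d.size
    dec, acc = d > 0, d < 0
    if not dec.any() and not acc.any():
        return {n: np.nan for n in names}
    sd1d2 = float(np.sum(d[dec] ** 2) / M)
    sd1a2 = float(np.sum(d[acc] ** 2) / M)
    sd1I2 = sd1d2 + sd1a2
    xm = v.mean()
    a = ((x - xm) + (y - xm)) / np.sqrt(2)  # along-identity excursion
    sd2d2 = float(np.sum(a[dec] ** 2) / M)
    sd2a2 = float(np.sum(a[acc] ** 2) / M)
    sd2I2 = sd2d2 + sd2a2
    sdnnd2 = (sd1d2 + sd2d2) / 2
    sdnna2 = (sd1a2 + sd2a2) / 2
    tot = sdnnd2 + sdnna2
    return {
        "GI": 100.0 * np.sum(np.abs(d[dec])) / np.sum(np.abs(d)),
        "C1d": sd1d2 / sd1I2 if sd1I2 > 0 else np.nan,
        "C1a": sd1a2 / sd1I2 if sd1I2 > 0 else np.nan,
        "SD1d": np.sqrt(sd1d2),
        "SD1a": np.sqrt(sd1a2),
        "C2d": sd2d2 / sd2I2 if sd2I2 > 0 else np.nan,
        "C2a": sd2a2 / sd2I2 if sd2I2 > 0 else np.nan,
        "SD2d": np.sqrt(sd2d2),
        "SD2a": np.sqrt(sd2a2),
        "SD2I": np.sqrt(sd2I2),
        "Cd": sdnnd2 / tot if tot > 0 else np.nan,
        "Ca": sdnna2 / tot if tot > 0 else np.nan,
        "SDNNd": np.sqrt(sdnnd2),
        "SDNNa": np.sqrt(sdnna2),
    }


# ------------------------------------------------------------- complexity

def sample_entropy(values: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Richman-Moorman sample entropy, Chebyshev distance, self-matches excluded."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 10:
        return np.nan
    r = r_factor * v.std()
    if v.std() < 1e-12:  # (numerically) constant series is perfectly regular
        return 0.0

    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(v, mm)
        t = len(templ)
        c = 0
        for i in range(t - 1):
            dist = np.max(np.abs(templ[i + 1 :] - templ[i]), axis=1)
            c += int(np.sum(dist <= r))
        return c

    # templates of a common count: use n-m windows for both lengths
    templ_m = np.lib.stride_tricks.sliding_window_view(v, m)[: n - m]
    b = 0
    for i in range(len(templ_m) - 1):
        b += int(np.sum(np.max(np.abs(templ_m[i + 1 :] - templ_m[i]), axis=1) <= r))
    a = _count(m + 1)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


# ------------------------------------------------- multi-scale windows

def multiscale_windows(
    epochs: list[EpochIntervals], i: int
) -> dict[int, tuple[list[np.ndarray], bool]]:
    """Per-epoch lists for the 1/2/5/10-min windows starting at epoch ``i``.

    window(k minutes) = epochs i..i+extra; truncated (and flagged) near the
    recording end.
    """
    if not 0 <= i < len(epochs):
        raise IndexError("epoch index out of range")
    out = {}
    for w, extra in WINDOW_EXTRA.items():
        hi = i + extra + 1
        truncated = hi > len(epochs)
        segs = [np.asarray(e.values, dtype=float) for e in epochs[i : min(hi, len(epochs))]]
        out[w] = (segs, truncated)
    return out


def _mode(v: np.ndarray) -> float:
    counts, edges = _hist(v)
    k = int(np.argmax(counts))
    return float((edges[k] + edges[k + 1]) / 2)


def window_time_domain(
    segments: list[np.ndarray], source: str = "JJ"
) -> dict[str, float]:
    """Window statistics; minutes are consecutive epoch pairs for SDANN/SDNNI."""
    names = ["Mean", "Median", "Mode", "Max", "Min", "MAD", "RMSSD", "SDNN",
             "SDSD", "CVNN", "CVSD", "SDANN", "SDNNI"]
    if source == "JJ":
        names += ["PNN50", "HR_Mean", "HR_Min", "HR_Max", "HR_Std"]
    v = np.concatenate(segments) if segments else np.array([])
    v = v[~np.isnan(v)]
    if v.size < 2:
        return {n: np.nan for n in names}
    base = time_domain(v, source=source)
    out = {n: base[n] for n in ["Mean", "Median", "Max", "Min", "MAD", "RMSSD",
                                "SDNN", "SDSD", "CVNN", "CVSD"]}
    out["Mode"] = _mode(v)
    if source == "JJ":
        for n in ["PNN50", "HR_Mean", "HR_Min", "HR_Max", "HR_Std"]:
            out[n] = base[n]
    minutes = [
        np.concatenate(segments[j : j + 2]) for j in range(0, len(segments) - 1, 2)
    ]
    minutes = [m[~np.isnan(m)] for m in minutes]
    minutes = [m for m in minutes if m.size >= 2]
    if len(minutes) >= 2:
        means = np.array([m.mean() for m in minutes])
        out["SDANN"] = float(means.std(ddof=1))
        out["SDNNI"] = float(np.mean([m.std(ddof=1) for m in minutes]))
    else:
        out["SDANN"] = out["SDNNI"] = np.nan
    return out


# ---------------------------------------------------------------- assembly

def epoch_features(
    jj: list[EpochIntervals], bb: list[EpochIntervals], i: int
) -> dict[str, float]:
    """All 232 registry features for epoch ``i``."""
    row: dict[str, float] = {}
    for src, epochs in (("JJ", jj), ("BB", bb)):
        v = np.asarray(epochs[i].values, dtype=float)
        td = time_domain(v, source=src)
        for k, val in td.items():
            row[f"{src}_{k}" if not k.startswith("HR_") else k] = val
        for k, val in frequency_domain(v).items():
            row[f"{src}_{k}"] = val
        for k, val in poincare(v).items():
            row[f"{src}_{k}"] = val
        row[f"{src}_SampEn"] = sample_entropy(v) if v.size else np.nan
        if src == "JJ":
            for k, val in asymmetry(v).items():
                row[f"JJ_{k}"] = val
        for w, (segs, _trunc) in multiscale_windows(epochs, i).items():
            wd = window_time_domain(segs, source=src)
            for k, val in wd.items():
                if k.startswith("HR_"):
                    row[f"HR_{w}min_{k[3:]}"] = val
                else:
                    row[f"{src}_{w}min_{k}"] = val
    return {name: row.get(name, np.nan) for name in REGISTRY_NAMES}


def assemble(
    jj: list[EpochIntervals],
    bb: list[EpochIntervals],
    stages: list[str] | None = None,
    impute: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table (epochs x 232 [+ stage]) and its imputation mask.

    Missing values are replaced by the column median over the recording;
    columns that are entirely missing fall back to 0.  The boolean mask
    marks imputed cells.
    """
    if len(jj) != len(bb):
        raise ValueError("JJ and BB must cover the same epoch grid")
    rows = [epoch_features(jj, bb, i) for i in range(len(jj))]
    table = pd.DataFrame(rows, columns=REGISTRY_NAMES)
    mask = table.isna()
    if impute:
        med = table.median()
        table = table.fillna(med).fillna(0.0)
    if stages is not None:
        if len(stages) != len(table):
            raise ValueError("one stage label per epoch required")
        table = pd.concat(
            [table, pd.Series(list(stages), name="stage", index=table.index)], axis=1
        )
    return table, mask
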