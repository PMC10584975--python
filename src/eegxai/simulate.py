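"""Simulation of labelled scalp EEG epochs with exact ground truth.

Three experimental conditions are generated, each a classification problem
whose discriminative feature is known by construction:

``temporal``
    Four classes of Gaussian-tapered ERP deflections differing in latency,
    polarity, or source location (sources from the packaged paracentral /
    cingulate dipole table).
``spectral``
    Four classes of band-limited oscillatory bursts (3-8, 8-13, 14-30,
    30-58 Hz) under a Gaussian envelope, sources drawn from the packaged
    sensorimotor dipole table.
``spatial``
    Two classes that differ only in source hemisphere; each epoch carries
    one ERP and one burst drawn from shared property laws.

Every epoch is 1 s at 250 Hz over 62 channels.  Brain noise is modelled as
(62 - n_signal_dipoles) pink-noise dipoles (5 uV RMS each) at random
locations on a cortical shell, forward-projected through the same head
model; the scalp-level signal-to-noise ratio is set exactly by power-ratio
mixing, and white sensor noise (10% of the mixed-epoch RMS) is added
last.  The per-trial
ground truth is the absolute forward projection of the signal waveform(s),
normalized to a maximum of 1.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .head_model import (
    LeadField,
    Montage,
    R_HEAD,
    build_default_montage,
    build_spherical_leadfield,
    dipole_gain,
    place_dipole,
    project_sources,
)

__all__ = [
    "FS",
    "N_SAMPLES",
    "ErpClassSpec",
    "BurstClassSpec",
    "EpochSet",
    "GroundTruthMap",
    "TEMPORAL_CLASSES",
    "SPECTRAL_CLASSES",
    "gaussian_peak",
    "band_burst",
    "pink_noise",
    "mix_to_snr",
    "signal_leadfield",
    "ground_truth_map",
    "generate_condition",
    "load_epochs",
    "save_epochs",
]

FS = 250.0
N_SAMPLES = 250
N_CHANNELS = 62
SNR_LEVELS_DB = (-3.5, -12.0, -16.0, -19.0, -23.0)

BRAIN_NOISE_RMS_UV = 5.0
#: white sensor noise, as an RMS fraction of the mixed scalp epoch (-20 dB).
#: Defined relative rather than absolute so that the scalp SNR grid — the
#: experiment's controlled variable — is set by the signal/brain-noise
#: mixing alone; the surrogate lead field's unit-norm columns make absolute
#: scalp amplitudes arbitrary, so an absolute sensor-noise level would
#: re-define the effective SNR.
SENSOR_NOISE_REL_RMS = 0.1
#: eccentricity (fraction of scalp radius) of the shell on which random
#: brain-noise dipoles are placed; approximates the cortical surface.
NOISE_SHELL_ECCENTRICITY = 0.80
#: relative threshold below which forward-projected ground truth is zeroed.
MASK_RTOL = 1e-12


@dataclass(frozen=True)
class ErpClassSpec:
    """Property law of one ERP class (jitters are uniform half-widths)."""

    class_id: int
    latency_ms: float
    latency_jitter_ms: float
    width_ms: float
    width_jitter_ms: float
    amplitude_range_uV: tuple[float, float]
    polarity: int
    source_pool: tuple[int, ...]  # 0-based rows of the ERP dipole table

    def __post_init__(self) -> None:
        if self.amplitude_range_uV[0] <= 0 or self.amplitude_range_uV[1] <= self.amplitude_range_uV[0]:
            raise ValueError("amplitude range must be positive and increasing")
        if self.latency_ms + self.width_ms / 2 > 1000.0:
            raise ValueError("ERP support must end by 1000 ms")


@dataclass(frozen=True)
class BurstClassSpec:
    """Property law of one oscillatory-burst class."""

    class_id: int
    band_hz: tuple[float, float]
    amplitude_range_uV: tuple[float, float]
    latency_range_ms: tuple[float, float]
    width_range_ms: tuple[float, float]
    source_pool: tuple[int, ...]  # 0-based rows of the sensorimotor table

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi < FS / 2):
            raise ValueError("band must satisfy 0 < lo < hi < Nyquist")
        if self.width_range_ms[1] > 1000.0:
            raise ValueError("burst width must fit the epoch")


_AMP_ERP = (1.0, 13.0)
TEMPORAL_CLASSES: tuple[ErpClassSpec, ...] = (
    ErpClassSpec(1, 60.0, 8.0, 50.0, 2.0, _AMP_ERP, +1, tuple(range(5))),
    ErpClassSpec(2, 900.0, 5.0, 100.0, 4.0, _AMP_ERP, +1, tuple(range(5))),
    ErpClassSpec(3, 500.0, 8.0, 100.0, 4.0, _AMP_ERP, -1, tuple(range(5))),
    ErpClassSpec(4, 500.0, 8.0, 100.0, 4.0, _AMP_ERP, -1, tuple(range(5, 10))),
)

_AMP_BURST = (0.5, 3.0)
_LAT_BURST = (200.0, 500.0)
_WID_BURST = (400.0, 600.0)
SPECTRAL_CLASSES: tuple[BurstClassSpec, ...] = (
    BurstClassSpec(1, (3.0, 8.0), _AMP_BURST, _LAT_BURST, _WID_BURST, tuple(range(14))),
    BurstClassSpec(2, (8.0, 13.0), _AMP_BURST, _LAT_BURST, _WID_BURST, tuple(range(14))),
    BurstClassSpec(3, (14.0, 30.0), _AMP_BURST, _LAT_BURST, _WID_BURST, tuple(range(14))),
    BurstClassSpec(4, (30.0, 58.0), _AMP_BURST, _LAT_BURST, _WID_BURST, tuple(range(14))),
)


@dataclass
class EpochSet:
    """Trials x samples x channels scalp EEG (uV) with labels and provenance."""

    data: np.ndarray  # (n_trials, 250, 62)
    labels: np.ndarray  # (n_trials,) integer class ids starting at 0
    condition: str
    snr_db: float
    seed: int
    metadata: pd.DataFrame  # per-trial source index, latency, width, amplitude, ...

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1:] != (N_SAMPLES, N_CHANNELS):
            raise ValueError("data must be (n_trials, 250, 62)")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class GroundTruthMap:
    """Per-trial ground-truth relevance on the input grid."""

    relevance: np.ndarray  # (n_trials, 250, 62) in [0, 1]
    mask: np.ndarray  # binary, same shape
    topo: np.ndarray  # (n_trials, 62) channel ground truth


def _table(name: str) -> pd.DataFrame:
    with resources.files("eegxai.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def erp_dipole_table() -> pd.DataFrame:
    """MNI coordinates of the 10 ERP sources (paracentral/cingulate region)."""
    return _table("table2_erp_dipoles.csv")


def sensorimotor_dipole_table() -> pd.DataFrame:
    """MNI coordinates of the 14 sensorimotor sources (spectral & spatial)."""
    return _table("table3_dipoles.csv")


def signal_leadfield(condition: str, montage: Montage | None = None) -> LeadField:
    """Surrogate lead field over the fixture dipoles of a condition.

    ``temporal`` uses the 10 ERP-table dipoles; ``spectral`` and ``spatial``
    use the 14 sensorimotor-table dipoles.  Columns follow table order.
    """
    montage = montage or build_default_montage()
    table = erp_dipole_table() if condition == "temporal" else sensorimotor_dipole_table()
    sources = [place_dipole((r.x, r.y, r.z)) for r in table.itertuples()]
    return build_spherical_leadfield(montage, sources)


def gaussian_peak(
    center_ms: float,
    width_ms: float,
    amplitude_uV: float,
    polarity: int = 1,
    fs: float = FS,
    n_samples: int = N_SAMPLES,
) -> np.ndarray:
    """Gaussian-tapered ERP deflection.

    The peak width is interpreted as the +-3 sigma support of the taper
    (sigma = width / 6) and the waveform is truncated to exactly that
    window, so the ground-truth support is compact; it attains exactly
    +-amplitude at the sample nearest the centre.
    """
    if width_ms <= 0:
        raise ValueError("width must be positive")
    t_ms = np.arange(n_samples) / fs * 1000.0
    sigma = width_ms / 6.0
    w = np.exp(-((t_ms - center_ms) ** 2) / (2 * sigma**2))
    peak = int(np.argmin(np.abs(t_ms - center_ms)))
    if w[peak] > 0:
        w = w / w[peak]
    w[np.abs(t_ms - center_ms) > width_ms / 2] = 0.0
    return polarity * amplitude_uV * w


def band_burst(
    band_hz: tuple[float, float],
    amplitude_uV: float,
    center_ms: float,
    width_ms: float,
    fs: float = FS,
    n_samples: int = N_SAMPLES,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Band-limited oscillatory burst under a Gaussian envelope.

    White noise is band-pass filtered (4th-order Butterworth, zero-phase),
    scaled to RMS ``amplitude_uV``, and multiplied by a unit-peak Gaussian
    envelope (sigma = width / 6), so the RMS near the envelope peak matches
    the requested amplitude.
    """
    lo, hi = band_hz
    if not (0 < lo < hi < fs / 2):
        raise ValueError("band must lie strictly below the Nyquist frequency")
    rng = rng or np.random.default_rng()
    if amplitude_uV == 0:
        return np.zeros(n_samples)
    # simulate with padding so the zero-phase filter has run-in room
    pad = n_samples
    white = rng.standard_normal(n_samples + 2 * pad)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, white)[pad:-pad]
    rms = np.sqrt(np.mean(carrier**2))
    if rms > 0:
        carrier = carrier / rms * amplitude_uV
    envelope = gaussian_peak(center_ms, width_ms, 1.0, +1, fs, n_samples)
    return carrier * envelope


def pink_noise(
    n_sources: int,
    n_samples: int,
    rms_uV: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f-amplitude noise rows, each rescaled to exactly ``rms_uV`` RMS.

    Spectral synthesis: the FFT of white noise is shaped by f^(-1/2)
    (power spectral density proportional to 1/f), the DC bin removed.
    """
    if rms_uV <= 0:
        raise ValueError("rms_uV must be positive")
    white = rng.standard_normal((n_sources, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5
    out = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    return out / rms * rms_uV


def mix_to_snr(signal_scalp: np.ndarray, noise_scalp: np.ndarray, snr_db: float) -> np.ndarray:
    """Mix projected signal and noise to an exact scalp SNR.

    The noise is rescaled so that the decibel ratio of mean squared
    amplitude over all samples and channels equals ``snr_db`` exactly:
    ``epoch = signal + beta * noise`` with
    ``10 log10(P_signal / (beta^2 P_noise)) = snr_db``.
    """
    if signal_scalp.shape != noise_scalp.shape:
        raise ValueError("signal and noise must have the same shape")
    p_sig = np.mean(signal_scalp**2)
    p_noi = np.mean(noise_scalp**2)
    if p_sig <= 0 or p_noi <= 0:
        raise ValueError("signal and noise must both have non-zero power")
    beta = np.sqrt(p_sig / (p_noi * 10.0 ** (snr_db / 10.0)))
    return signal_scalp + beta * noise_scalp


def ground_truth_map(
    leadfield: LeadField,
    source_idx,
    signal_waveform: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-project the signal waveform(s) into a normalized relevance map.

    Parameters
    ----------
    source_idx : int or sequence of ints (one per waveform row).
    signal_waveform : (n_samples,) or (n_used, n_samples) tapered signal.

    Returns
    -------
    relevance : (250, 62) absolute projection divided by its maximum.
    mask : binary support of the relevance (values below ``MASK_RTOL``
        relative to the maximum count as zero).
    topo : (62,) channel ground truth: absolute relevance summed over
        time, divided by its maximum — the same reduction applied to
        attribution maps in the spatial condition, so the ground truth
        scores a cosine similarity of exactly 1 against itself.
    """
    idx = np.atleast_1d(np.asarray(source_idx, dtype=int))
    w = np.atleast_2d(np.asarray(signal_waveform, dtype=float))
    proj = project_sources(leadfield, idx, w)
    relevance = np.abs(proj)
    peak = relevance.max()
    if peak == 0:
        raise ValueError("signal waveform is identically zero")
    relevance = relevance / peak
    relevance[relevance < MASK_RTOL] = 0.0
    mask = (relevance > 0).astype(np.uint8)
    topo = relevance.sum(axis=0)
    topo = topo / topo.max()
    return relevance, mask, topo


def _noise_shell_gains(montage: Montage, n_dipoles: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm, average-referenced gains of random radial shell dipoles."""
    v = rng.standard_normal((n_dipoles, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos = v * NOISE_SHELL_ECCENTRICITY * R_HEAD
    g = dipole_gain(montage, pos, v)
    g -= g.mean(axis=0, keepdims=True)
    g /= np.linalg.norm(g, axis=0, keepdims=True)
    return g


def _spatial_hemisphere_pools() -> tuple[np.ndarray, np.ndarray]:
    table = sensorimotor_dipole_table()
    left = np.flatnonzero(table.x.to_numpy() < 0)
    right = np.flatnonzero(table.x.to_numpy() > 0)
    return left, right


def generate_condition(
    condition: str,
    snr_db: float,
    n_per_class: int,
    seed: int,
    leadfield: LeadField | None = None,
) -> tuple[EpochSet, GroundTruthMap]:
    """Generate a balanced labelled epoch set plus its ground truth.

    Deterministic given ``(condition, snr_db, n_per_class, seed)``.  The
    returned trials are ordered class-major (all class-1 trials first);
    shuffling is deferred to cross-validation, which stratifies anyway.
    """
    if condition not in ("temporal", "spectral", "spatial"):
        raise ValueError(f"unknown condition {condition!r}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    montage = leadfield.montage if leadfield is not None else build_default_montage()
    lf = leadfield if leadfield is not None else signal_leadfield(condition, montage)
    cond_id = {"temporal": 1, "spectral": 2, "spatial": 3}[condition]
    rng = np.random.default_rng(
        np.random.SeedSequence([cond_id, int(n_per_class), int(seed), int(round(10 * snr_db)) & 0xFFFF])
    )

    if condition == "temporal":
        class_specs: tuple = TEMPORAL_CLASSES
        n_signal = 1
    elif condition == "spectral":
        class_specs = SPECTRAL_CLASSES
        n_signal = 1
    else:
        class_specs = (0, 1)  # left / right hemisphere
        n_signal = 2

    n_classes = len(class_specs)
    n_trials = n_classes * n_per_class
    data = np.empty((n_trials, N_SAMPLES, N_CHANNELS), dtype=np.float64)
    relevance = np.empty_like(data)
    mask = np.empty(data.shape, dtype=np.uint8)
    topo = np.empty((n_trials, N_CHANNELS))
    labels = np.repeat(np.arange(n_classes), n_per_class)
    meta_rows: list[dict] = []

    n_noise = N_CHANNELS - n_signal
    left_pool, right_pool = _spatial_hemisphere_pools()

    trial = 0
    for ci, spec in enumerate(class_specs):
        for _ in range(n_per_class):
            if condition == "temporal":
                lat = spec.latency_ms + rng.uniform(-1, 1) * spec.latency_jitter_ms
                wid = spec.width_ms + rng.uniform(-1, 1) * spec.width_jitter_ms
                amp = rng.uniform(*spec.amplitude_range_uV)
                src = int(rng.choice(spec.source_pool))
                wave = gaussian_peak(lat, wid, amp, spec.polarity)[None, :]
                src_idx = [src]
                meta = dict(source=src, latency_ms=lat, width_ms=wid, amplitude_uV=amp)
            elif condition == "spectral":
                lat = rng.uniform(*spec.latency_range_ms)
                wid = rng.uniform(*spec.width_range_ms)
                amp = rng.uniform(*spec.amplitude_range_uV)
                src = int(rng.choice(spec.source_pool))
                wave = band_burst(spec.band_hz, amp, lat, wid, rng=rng)[None, :]
                src_idx = [src]
                meta = dict(source=src, latency_ms=lat, width_ms=wid, amplitude_uV=amp)
            else:  # spatial: one ERP + one burst from one hemisphere
                pool = left_pool if ci == 0 else right_pool
                erp_lat = 500.0 + rng.uniform(-1, 1) * 8.0
                erp_wid = 100.0 + rng.uniform(-1, 1) * 4.0
                erp_amp = rng.uniform(1.0, 13.0)
                burst_lat = rng.uniform(*_LAT_BURST)
                burst_wid = rng.uniform(*_WID_BURST)
                burst_amp = rng.uniform(*_AMP_BURST)
                src_erp = int(rng.choice(pool))
                src_burst = int(rng.choice(pool))
                wave = np.vstack(
                    [
                        gaussian_peak(erp_lat, erp_wid, erp_amp, +1),
                        band_burst((8.0, 13.0), burst_amp, burst_lat, burst_wid, rng=rng),
                    ]
                )
                src_idx = [src_erp, src_burst]
                meta = dict(
                    source=src_erp, source_burst=src_burst,
                    latency_ms=erp_lat, width_ms=erp_wid, amplitude_uV=erp_amp,
                    burst_latency_ms=burst_lat, burst_width_ms=burst_wid,
                    burst_amplitude_uV=burst_amp,
                )

            sig_scalp = project_sources(lf, src_idx, wave)
            noise_gain = _noise_shell_gains(montage, n_noise, rng)
            noise_src = pink_noise(n_noise, N_SAMPLES, BRAIN_NOISE_RMS_UV, rng)
            noise_scalp = (noise_gain @ noise_src).T
            epoch = mix_to_snr(sig_scalp, noise_scalp, snr_db)
            sensor_rms = SENSOR_NOISE_REL_RMS * np.sqrt(np.mean(epoch**2))
            epoch = epoch + rng.standard_normal(epoch.shape) * sensor_rms
            data[trial] = epoch
            rel, msk, tp = ground_truth_map(lf, src_idx, wave)
            relevance[trial], mask[trial], topo[trial] = rel, msk, tp
            meta.update(trial=trial, class_id=ci)
            meta_rows.append(meta)
            trial += 1

    epochs = EpochSet(
        data=data,
        labels=labels,
        condition=condition,
        snr_db=float(snr_db),
        seed=int(seed),
        metadata=pd.DataFrame(meta_rows),
    )
    gt = GroundTruthMap(relevance=relevance, mask=mask, topo=topo)
    return epochs, gt


def save_epochs(path, epochs: EpochSet, gt: GroundTruthMap) -> None:
    """Persist an epoch set and its ground truth to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data.astype(np.float32))
        fh.create_dataset("labels", data=epochs.labels.astype(np.int64))
        fh.create_dataset("gt_relevance", data=gt.relevance.astype(np.float32))
        fh.create_dataset("gt_mask", data=gt.mask)
        fh.create_dataset("gt_topo", data=gt.topo.astype(np.float32))
        fh.attrs["condition"] = epochs.condition
        fh.attrs["snr_db"] = epochs.snr_db
        fh.attrs["seed"] = epochs.seed
        fh.attrs["fs"] = FS
        fh.create_dataset("metadata_json", data=epochs.metadata.to_json(orient="split"))


def load_epochs(path) -> tuple[EpochSet, GroundTruthMap]:
    """Load an epoch set written by :func:`save_epochs`."""
    from io import StringIO

    with h5py.File(path, "r") as fh:
        raw = fh["metadata_json"][()]
        meta = pd.read_json(StringIO(raw.decode() if isinstance(raw, bytes) else raw),
                            orient="split")
        epochs = EpochSet(
            data=np.asarray(fh["data"], dtype=np.float64),
            labels=np.asarray(fh["labels"], dtype=np.int64),
            condition=str(fh.attrs["condition"]),
            snr_db=float(fh.attrs["snr_db"]),
            seed=int(fh.attrs["seed"]),
            metadata=meta,
        )
        gt = GroundTruthMap(
            relevance=np.asarray(fh["gt_relevance"], dtype=np.float64),
            mask=np.asarray(fh["gt_mask"], dtype=np.uint8),
            topo=np.asarray(fh["gt_topo"], dtype=np.float64),
        )
    return epochs, gt
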