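"""Electrode montage and surrogate spherical head model.

The scalp is modelled as a single homogeneous conducting sphere of radius
``R_HEAD`` (85 mm).  The potential generated on the sphere surface by a
current dipole inside it has an exact Legendre-series solution; the series
is evaluated directly, which keeps the model free of mesh or BEM machinery
while still producing the volume-conduction smearing that makes scalp EEG
spatially blurred.  A realistic lead field (e.g. from a boundary-element
head model) can be substituted at any point via :func:`load_leadfield`.

Conventions
-----------
* Coordinates are in mm, RAS-oriented (x: left->right, y: posterior->
  anterior, z: inferior->superior), origin at the sphere centre.
* Gain matrices are channels x sources.  Each column is average-referenced
  (zero mean over channels) and scaled to unit L2 norm, so source waveform
  amplitudes (uV dipole moment) set the scalp scale at projection time.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "R_HEAD",
    "Montage",
    "DipoleSource",
    "LeadField",
    "build_default_montage",
    "place_dipole",
    "dipole_gain",
    "build_spherical_leadfield",
    "load_leadfield",
    "save_leadfield",
    "project_sources",
]

logger = logging.getLogger(__name__)

R_HEAD = 85.0
"""Scalp sphere radius in mm."""

#: MNI coordinates are mapped into the sphere by dividing by this half-width
#: (mm) before rescaling to R_HEAD; ~88 mm is the maximal MNI head half-width.
MNI_SCALE = 88.0

#: Maximum dipole eccentricity (fraction of R_HEAD); positions mapping
#: outside are clipped here to keep the Legendre series convergent.
MAX_ECCENTRICITY = 0.95

_CONDUCTIVITY = 0.33  # S/m, homogeneous brain/scalp compartment


@dataclass(frozen=True)
class Montage:
    """A named set of electrodes on the scalp sphere."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), mm, on the sphere surface

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def unit_positions(self) -> np.ndarray:
        """Positions divided by R_HEAD (unit vectors)."""
        return self.positions / R_HEAD

    def hemisphere_index(self) -> np.ndarray:
        """Sign of the x coordinate per channel (-1 left, 0 midline, +1 right)."""
        return np.sign(np.round(self.positions[:, 0], 6))


@dataclass(frozen=True)
class DipoleSource:
    """A current dipole inside the head sphere."""

    mni_xyz: tuple[float, float, float]
    position: np.ndarray  # mm, inside the sphere
    orientation: np.ndarray  # unit 3-vector
    role: str = "signal"  # "signal" | "brain-noise"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        ori = np.asarray(self.orientation, dtype=float)
        if not np.isfinite(pos).all() or not np.isfinite(ori).all():
            raise ValueError("dipole position/orientation must be finite")
        n = np.linalg.norm(ori)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("orientation must be unit norm")
        if np.linalg.norm(pos) >= R_HEAD:
            raise ValueError("dipole must lie strictly inside the head sphere")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori)


@dataclass
class LeadField:
    """Linear map from dipole source moments to scalp potentials."""

    gain: np.ndarray  # (n_channels, n_sources)
    sources: list[DipoleSource]
    montage: Montage

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if g.shape != (self.montage.n_channels, len(self.sources)):
            raise ValueError(
                f"gain shape {g.shape} does not match "
                f"{self.montage.n_channels} channels x {len(self.sources)} sources"
            )
        if not np.isfinite(g).all():
            raise ValueError("gain must be finite")
        if (np.linalg.norm(g, axis=0) == 0).any():
            raise ValueError("every gain column must be non-zero")
        self.gain = g

    @property
    def n_channels(self) -> int:
        return self.montage.n_channels

    @property
    def n_sources(self) -> int:
        return len(self.sources)


def _data_path(name: str):
    return resources.files("eegxai.data").joinpath(name)


def build_default_montage() -> Montage:
    """Load the packaged 62-electrode 10-10 montage.

    The fixture holds 62 standard actiCAP-style sites (a 64-channel cap
    minus the two ear-adjacent electrodes absent from realistic forward
    models), with positions on the 85 mm scalp sphere.
    """
    path = _data_path("montage62.tsv")
    try:
        raw = path.read_text()
    except FileNotFoundError as err:  # pragma: no cover
        raise RuntimeError("montage fixture montage62.tsv is missing") from err
    labels: list[str] = []
    pos: list[list[float]] = []
    lines = raw.strip().splitlines()
    if not lines or lines[0].split("\t") != ["label", "x", "y", "z"]:
        raise RuntimeError("montage fixture montage62.tsv is corrupt")
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != 4:
            raise RuntimeError("montage fixture montage62.tsv is corrupt")
        labels.append(parts[0])
        pos.append([float(v) for v in parts[1:]])
    # re-project onto the sphere exactly (the fixture stores rounded mm)
    arr = np.asarray(pos)
    arr = arr / np.linalg.norm(arr, axis=1, keepdims=True) * R_HEAD
    montage = Montage(labels=labels, positions=arr)
    if montage.n_channels != 62:
        raise RuntimeError("montage fixture must contain exactly 62 channels")
    return montage


def place_dipole(mni_xyz, role: str = "signal") -> DipoleSource:
    """Map an MNI coordinate (mm) to a radially oriented dipole in the sphere.

    The MNI position is scaled by ``R_HEAD / MNI_SCALE``; positions landing
    outside ``MAX_ECCENTRICITY * R_HEAD`` are clipped onto that shell (with
    a logged warning).  Orientation is radial ("perpendicular to the scalp"),
    defaulting to +z for a dipole at the origin.
    """
    xyz = np.asarray(mni_xyz, dtype=float)
    if xyz.shape != (3,) or not np.isfinite(xyz).all():
        raise ValueError("mni_xyz must be a finite 3-vector")
    pos = xyz / MNI_SCALE * R_HEAD
    r = np.linalg.norm(pos)
    rmax = MAX_ECCENTRICITY * R_HEAD
    if r > rmax:
        logger.warning(
            "dipole at MNI %s maps outside the head sphere; clipping to %.0f%% radius",
            tuple(xyz), 100 * MAX_ECCENTRICITY,
        )
        pos = pos / r * rmax
        r = rmax
    if r < 1e-9:
        ori = np.array([0.0, 0.0, 1.0])
    else:
        ori = pos / r
    return DipoleSource(mni_xyz=tuple(xyz), position=pos, orientation=ori, role=role)


def _legendre_terms(f: float) -> int:
    """Number of series terms for eccentricity ``f`` (truncation < 1e-12)."""
    f = min(max(f, 1e-6), MAX_ECCENTRICITY)
    n = int(np.ceil(np.log(1e-12) / np.log(f))) + 10
    return min(max(n, 30), 800)


def dipole_gain(montage: Montage, positions: np.ndarray, orientations: np.ndarray) -> np.ndarray:
    """Raw (un-normalized) surface potentials of dipoles in a homogeneous sphere.

    Evaluates the exact Legendre expansion of the surface potential of a
    current dipole inside a homogeneous conducting sphere,

        V = 1/(4 pi sigma R^2) * sum_n (2n+1)/n * f^(n-1)
            * [ n * p_r * P_n(cos g) + p_t * P_n^1(cos g) ],

    with f the dipole eccentricity, ``p_r``/``p_t`` the radial and
    tangential moment components in the dipole-electrode plane and ``g``
    the angle between dipole position and electrode.

    Parameters
    ----------
    positions : (S, 3) dipole positions in mm.
    orientations : (S, 3) unit moment directions.

    Returns
    -------
    gain : (n_channels, S) array.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    ori = np.atleast_2d(np.asarray(orientations, dtype=float))
    if pos.shape != ori.shape or pos.shape[1] != 3:
        raise ValueError("positions and orientations must both be (S, 3)")
    r = np.linalg.norm(pos, axis=1)
    if (r >= R_HEAD).any():
        raise ValueError("dipole at or beyond the electrode radius")
    f = r / R_HEAD  # eccentricities
    e = montage.unit_positions()  # (C, 3)
    C, S = e.shape[0], pos.shape[0]

    # unit vector from origin to each dipole; arbitrary for origin dipoles
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(r[:, None] > 1e-12, pos / np.maximum(r[:, None], 1e-12),
                        np.array([0.0, 0.0, 1.0]))
    cosg = np.clip(e @ rhat.T, -1.0, 1.0)  # (C, S)
    # radial and tangential moment components; the tangential direction is
    # taken in the plane spanned by rhat and the electrode direction.
    p_r = np.einsum("sj,sj->s", ori, rhat)  # (S,)
    # tangential unit vector t = (e - cosg*rhat)/sing per (C,S) pair
    sing = np.sqrt(np.maximum(1.0 - cosg**2, 0.0))
    e_exp = e[:, None, :]  # (C,1,3)
    t_vec = e_exp - cosg[:, :, None] * rhat[None, :, :]
    tnorm = np.linalg.norm(t_vec, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_hat = np.where(tnorm[:, :, None] > 1e-12, t_vec / np.maximum(tnorm[:, :, None], 1e-12), 0.0)
    p_t = np.einsum("csj,sj->cs", t_hat, ori)  # (C, S)

    n_terms = _legendre_terms(float(f.max()) if S else 0.5)
    # Legendre recurrences for P_n(x) and P_n^1(x), vectorized over (C,S)
    x = cosg
    Pnm1 = np.ones_like(x)      # P_0
    Pn = x.copy()               # P_1
    P1nm1 = np.zeros_like(x)    # P_0^1
    P1n = sing.copy()           # P_1^1 = sin
    V = np.zeros((C, S))
    fpow = np.ones(S)  # f^(n-1)
    for n in range(1, n_terms + 1):
        coef = (2 * n + 1) / n
        V += coef * fpow[None, :] * (n * p_r[None, :] * Pn + p_t * P1n)
        fpow = fpow * f
        # advance recurrences to order n+1
        Pnp1 = ((2 * n + 1) * x * Pn - n * Pnm1) / (n + 1)
        P1np1 = ((2 * n + 1) * x * P1n - (n + 1) * P1nm1) / n
        Pnm1, Pn = Pn, Pnp1
        P1nm1, P1n = P1n, P1np1
    scale = 1.0 / (4 * np.pi * _CONDUCTIVITY * (R_HEAD / 1000.0) ** 2)
    return V * scale


def build_spherical_leadfield(montage: Montage, sources: list[DipoleSource]) -> LeadField:
    """Assemble the surrogate lead field for a list of dipoles.

    Each gain column is the analytic spherical-head potential of its dipole,
    average-referenced (zero mean across channels) and scaled to unit L2
    norm so that source amplitudes in uV set the scalp scale at projection
    time.
    """
    if not sources:
        raise ValueError("at least one source is required")
    pos = np.array([s.position for s in sources])
    ori = np.array([s.orientation for s in sources])
    gain = dipole_gain(montage, pos, ori)
    gain = gain - gain.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(gain, axis=0)
    if (norms < 1e-300).any():
        raise ValueError("degenerate (zero) gain column; dipole too close to centre?")
    gain = gain / norms
    return LeadField(gain=gain, sources=list(sources), montage=montage)


def save_leadfield(leadfield: LeadField, path) -> None:
    """Write a lead field to HDF5 (datasets: gain, positions, orientations, labels)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("gain", data=leadfield.gain.astype(np.float64))
        fh.create_dataset("positions", data=np.array([s.position for s in leadfield.sources]))
        fh.create_dataset("orientations", data=np.array([s.orientation for s in leadfield.sources]))
        fh.create_dataset(
            "labels", data=np.array(leadfield.montage.labels, dtype=h5py.string_dtype())
        )
        fh.create_dataset("channel_positions", data=leadfield.montage.positions)


def load_leadfield(path, montage: Montage | None = None) -> LeadField:
    """Load a (possibly user-supplied) lead field from HDF5.

    The file must contain datasets ``gain`` (channels x sources),
    ``positions``, ``orientations`` and ``labels``; the channel count must
    match the montage (the packaged 62-channel montage by default).
    """
    path = Path(path)
    with h5py.File(path, "r") as fh:
        for key in ("gain", "positions", "orientations", "labels"):
            if key not in fh:
                raise ValueError(f"lead field file {path} is missing dataset '{key}'")
        gain = np.asarray(fh["gain"], dtype=float)
        positions = np.asarray(fh["positions"], dtype=float)
        orientations = np.asarray(fh["orientations"], dtype=float)
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["labels"][()]]
        ch_pos = np.asarray(fh["channel_positions"]) if "channel_positions" in fh else None
    if montage is None:
        if ch_pos is not None and len(labels) == len(ch_pos):
            montage = Montage(labels=labels, positions=ch_pos)
        else:
            montage = build_default_montage()
    if gain.ndim != 2 or gain.shape[0] != montage.n_channels:
        raise ValueError(
            f"gain has {gain.shape[0] if gain.ndim == 2 else '?'} rows; "
            f"montage defines {montage.n_channels} channels"
        )
    if not np.isfinite(gain).all():
        raise ValueError("gain contains non-finite values")
    if positions.shape != (gain.shape[1], 3) or orientations.shape != (gain.shape[1], 3):
        raise ValueError("positions/orientations must be (n_sources, 3)")
    sources = [
        DipoleSource(mni_xyz=tuple(p), position=p, orientation=o / np.linalg.norm(o))
        for p, o in zip(positions, orientations)
    ]
    return LeadField(gain=gain, sources=sources, montage=montage)


def project_sources(leadfield: LeadField, source_indices, waveforms: np.ndarray) -> np.ndarray:
    """Forward-project source waveforms to the scalp.

    Parameters
    ----------
    source_indices : sequence of column indices into the lead field.
    waveforms : (n_used_sources, n_samples) dipole moment time courses (uV).

    Returns
    -------
    scalp : (n_samples, n_channels) array, ``scalp[t, c] = sum_s G[c, s] w[s, t]``.
    """
    idx = np.asarray(source_indices, dtype=int)
    if idx.ndim != 1:
        raise ValueError("source_indices must be one-dimensional")
    if (idx < 0).any() or (idx >= leadfield.n_sources).any():
        raise IndexError("source index out of range")
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.shape[0] != idx.size:
        raise ValueError("waveforms must be (n_used_sources, n_samples)")
    return (leadfield.gain[:, idx] @ w).T
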