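"""Spherical head models and leadfields.

The forward model maps dipole moments at grid locations inside the brain to
scalp potentials. A concentric three-shell sphere (brain, skull, scalp) is
solved analytically: the potential of a current dipole is expanded in Legendre
harmonics and the per-order radial coefficients are obtained from the
interface continuity conditions, giving the classical truncated-series
leadfield. Externally computed leadfields can be imported from an HDF5
container instead.

Coordinates are RAS, millimetres, origin at the sphere centre. Gains are
stored average-referenced: every gain column sums to zero across channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: Default shell radii in mm (brain, skull, scalp) — standard adult sphere fit.
DEFAULT_SHELL_RADII_MM = (80.0, 85.0, 92.0)

#: Default shell conductivities in S/m (brain, skull, scalp).
DEFAULT_CONDUCTIVITIES = (0.33, 0.01, 0.43)

#: Default source-grid spacing in mm (1.5 cm voxels).
DEFAULT_GRID_SPACING_MM = 15.0

#: 31 EEG channels of a standard 32-channel MR-compatible cap (FCz reference).
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2",
)


@dataclass
class SensorArray:
    """EEG electrode set on the scalp sphere.

    Parameters
    ----------
    names : list of str
        Unique 10/20 channel labels.
    positions : ndarray, shape (n_channels, 3)
        Electrode positions in mm, normalised to the scalp radius.
    reference : str
        Label of the recording reference (not among ``names``).
    """

    names: list[str]
    positions: np.ndarray
    reference: str = "FCz"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.names), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return len(self.names)


def standard_sensor_array(
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    scalp_radius_mm: float = DEFAULT_SHELL_RADII_MM[-1],
    reference: str = "FCz",
) -> SensorArray:
    """Build a :class:`SensorArray` from the standard easycap 10/20 montage.

    Template electrode positions are taken from MNE's built-in ``easycap-M1``
    montage and projected radially onto the scalp sphere.
    """
    import mne

    montage = mne.channels.make_standard_montage("easycap-M1")
    ch_pos = montage.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in ch_pos]
    if missing:
        raise ValueError(f"channels not in easycap-M1 montage: {missing}")
    pos = np.array([ch_pos[c] for c in channels], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorArray(list(channels), pos * scalp_radius_mm, reference=reference)


def read_montage(path) -> SensorArray:
    """Read a plain-text montage file with lines ``name x y z`` (mm)."""
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed montage line: {line!r}")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return SensorArray(names, np.array(rows))


def write_montage(path, sensors: SensorArray) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference {sensors.reference}\n")
        for name, (x, y, z) in zip(sensors.names, sensors.positions):
            fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


@dataclass
class Leadfield:
    """Sensor gain matrix over a 3D source grid.

    ``gain`` has shape (n_channels, n_sources * 3); the three consecutive
    columns of source *v* are its x/y/z dipole orientations. ``grid`` holds
    source coordinates in mm. Gains are average-referenced.
    """

    gain: np.ndarray
    grid: np.ndarray
    spacing_mm: float
    conductivities: tuple[float, ...]
    channel_names: list[str]
    shell_radii_mm: tuple[float, ...] = DEFAULT_SHELL_RADII_MM
    reference_scheme: str = "average"

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.grid.shape[0]

    def validate(self) -> None:
        if self.gain.shape != (len(self.channel_names), 3 * self.grid.shape[0]):
            raise ValueError(
                f"gain shape {self.gain.shape} inconsistent with "
                f"{len(self.channel_names)} channels and {self.grid.shape[0]} sources"
            )
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield gains must be finite")
        radii = np.linalg.norm(self.grid, axis=1)
        if self.grid.size and radii.max() >= self.shell_radii_mm[0]:
            raise ValueError("source grid extends outside the innermost shell")
        if self.reference_scheme == "average":
            colsum = np.abs(self.gain.sum(axis=0))
            scale = np.abs(self.gain).max() or 1.0
            if self.gain.size and colsum.max() > 1e-8 * scale:
                raise ValueError(
                    "average-referenced gain columns must sum to zero across channels"
                )

    def gain_at(self, source_index: int) -> np.ndarray:
        """(n_channels, 3) gain block of one source."""
        return self.gain[:, 3 * source_index : 3 * source_index + 3]

    def nearest_source(self, location_mm) -> tuple[int, float]:
        """Index of and distance to the grid point nearest ``location_mm``."""
        d = np.linalg.norm(self.grid - np.asarray(location_mm, float), axis=1)
        idx = int(np.argmin(d))
        return idx, float(d[idx])


def make_source_grid(
    inner_radius_mm: float, spacing_mm: float, drop_centre: bool = True
) -> np.ndarray:
    """Cubic lattice of points strictly inside the innermost shell.

    Grid indices map to coordinates via ``spacing * index`` around the origin
    (0-based symmetric lattice). The centre point is dropped because the
    tangential dipole field is undefined there.
    """
    k = int(np.floor((inner_radius_mm - 1e-9) / spacing_mm))
    ax = np.arange(-k, k + 1) * spacing_mm
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    keep = r < inner_radius_mm
    if drop_centre:
        centre = r < 1e-12
        if centre.any():
            logger.info("dropping %d grid point(s) at the sphere centre", centre.sum())
        keep &= ~centre
    return pts[keep]


def _shell_coefficients(
    n_terms: int, shell_radii_mm: tuple[float, ...], conductivities: tuple[float, ...]
) -> np.ndarray:
    """Per-order surface transfer coefficients c_n for the multishell sphere.

    For each harmonic order n, the potential in shell j is
    ``S (R/r)^(n+1) + A_j (r/R)^n + B_j (R/r)^(n+1)`` (the primary term S only
    in the innermost shell). Interface continuity of potential and radial
    current plus the insulating outer boundary give a small linear system;
    c_n is the surface value for a unit primary coefficient.
    """
    radii = np.asarray(shell_radii_mm, dtype=float)
    sig = np.asarray(conductivities, dtype=float)
    if len(radii) != len(sig):
        raise ValueError("need one conductivity per shell")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("shell radii must be strictly increasing")
    if np.any(sig <= 0):
        raise ValueError("conductivities must be positive")
    L = len(radii)
    R = radii[-1]
    rho = radii / R
    c = np.empty(n_terms + 1)
    c[0] = 0.0
    for n in range(1, n_terms + 1):
        # unknowns: A_1, then (A_j, B_j) for j = 2..L
        m = 2 * L - 1
        M = np.zeros((m, m))
        rhs = np.zeros(m)

        def acol(j):  # column of A_j
            return 0 if j == 1 else 2 * j - 3

        def bcol(j):  # column of B_j (j >= 2)
            return 2 * j - 2

        row = 0
        for j in range(1, L):
            p = rho[j - 1] ** n
            q = rho[j - 1] ** -(n + 1)
            # potential continuity at interface j
            M[row, acol(j)] += p
            if j >= 2:
                M[row, bcol(j)] += q
            M[row, acol(j + 1)] -= p
            M[row, bcol(j + 1)] -= q
            if j == 1:
                rhs[row] = -q  # primary term S=1 lives in shell 1
            row += 1
            # radial current continuity (r * dV/dr matched, scaled by sigma)
            M[row, acol(j)] += sig[j - 1] * n * p
            if j >= 2:
                M[row, bcol(j)] += -sig[j - 1] * (n + 1) * q
            M[row, acol(j + 1)] -= sig[j] * n * p
            M[row, bcol(j + 1)] -= -sig[j] * (n + 1) * q
            if j == 1:
                rhs[row] = sig[0] * (n + 1) * q
            row += 1
        # insulating outer boundary at rho = 1
        M[row, acol(L)] = n
        if L >= 2:
            M[row, bcol(L)] = -(n + 1)
            rhs[row] = 0.0
        else:
            rhs[row] = n + 1  # primary reaches the surface directly
        sol = np.linalg.solve(M, rhs)
        surf = sol[acol(L)]
        if L >= 2:
            surf += sol[bcol(L)]
        else:
            surf += 1.0  # primary term at rho = 1
        c[n] = surf
    return c


def build_spherical_leadfield(
    sensors: SensorArray,
    shell_radii_mm: tuple[float, ...] = DEFAULT_SHELL_RADII_MM,
    shell_conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES,
    grid_spacing_mm: float = DEFAULT_GRID_SPACING_MM,
    n_terms: int = 100,
    grid: np.ndarray | None = None,
) -> Leadfield:
    """Analytic multishell-sphere leadfield on a cubic source grid.

    The scalp potential of a dipole at radius b with moment q is

    ``V(e) = (1 / 4 pi sigma_1 R^2) * sum_n c_n (b/R)^(n-1)
    [ n P_n(u) (q . r0_hat) + P_n'(u) (q . re_hat - u q . r0_hat) ]``

    where u is the cosine of the angle between dipole and electrode
    directions and c_n the shell transfer coefficients. The series is
    truncated at ``n_terms`` (>= 60 recommended). Gains are returned
    average-referenced.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    radii = tuple(float(r) for r in shell_radii_mm)
    sig = tuple(float(s) for s in shell_conductivities)
    if grid is None:
        grid = make_source_grid(radii[0], grid_spacing_mm)
    else:
        grid = np.asarray(grid, dtype=float)
        r = np.linalg.norm(grid, axis=1)
        centre = r < 1e-12
        if centre.any():
            logger.info("dropping %d source(s) at the sphere centre", centre.sum())
            grid = grid[~centre]
            r = r[~centre]
        if grid.size and r.max() >= radii[0]:
            raise ValueError("sources must lie strictly inside the innermost shell")

    R = radii[-1]
    c = _shell_coefficients(n_terms, radii, sig)

    e_hat = sensors.positions / np.linalg.norm(sensors.positions, axis=1, keepdims=True)
    b = np.linalg.norm(grid, axis=1)  # (n_src,)
    r0_hat = grid / b[:, None]  # (n_src, 3)
    u = r0_hat @ e_hat.T  # (n_src, n_el)
    x = b / R  # (n_src,)

    n_src, n_el = u.shape
    # Accumulate sum_n c_n x^(n-1) [ n P_n(u) r0_hat + P_n'(u) (e_hat - u r0_hat) ]
    coef_rad = np.zeros((n_src, n_el))  # multiplies r0_hat
    coef_ele = np.zeros((n_src, n_el))  # multiplies e_hat
    P_prev = np.ones_like(u)  # P_0
    P_cur = u.copy()  # P_1
    dP_prev = np.zeros_like(u)  # P_0'
    dP_cur = np.ones_like(u)  # P_1'
    xpow = np.ones(n_src)  # x^(n-1)
    for n in range(1, n_terms + 1):
        w = c[n] * xpow  # (n_src,)
        coef_rad += w[:, None] * (n * P_cur - u * dP_cur)
        coef_ele += w[:, None] * dP_cur
        # advance recurrences to order n+1
        P_next = ((2 * n + 1) * u * P_cur - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        dP_prev, dP_cur = dP_cur, dP_next
        xpow = xpow * x

    scale = 1.0 / (4.0 * np.pi * sig[0] * R**2)
    # gain[e, 3v + o] = scale * (coef_rad[v, e] r0_hat[v, o] + coef_ele[v, e] e_hat[e, o])
    gain = scale * (
        coef_rad.transpose(1, 0)[:, :, None] * r0_hat[None, :, :]
        + coef_ele.transpose(1, 0)[:, :, None] * e_hat[:, None, :]
    )  # (n_el, n_src, 3)
    gain = gain.reshape(n_el, 3 * n_src)
    gain = gain - gain.mean(axis=0, keepdims=True)  # average reference
    return Leadfield(
        gain=gain,
        grid=grid,
        spacing_mm=float(grid_spacing_mm),
        conductivities=sig,
        channel_names=list(sensors.names),
        shell_radii_mm=radii,
        reference_scheme="average",
    )


def export_leadfield(path, lf: Leadfield) -> None:
    """Write a leadfield to the HDF5 container (datasets /gain, /grid)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("grid", data=lf.grid)
        f.create_dataset(
            "channel_names", data=np.array(lf.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["spacing_mm"] = lf.spacing_mm
        f.attrs["conductivities"] = list(lf.conductivities)
        f.attrs["shell_radii_mm"] = list(lf.shell_radii_mm)
        f.attrs["reference"] = lf.reference_scheme


def import_leadfield(path) -> Leadfield:
    """Load and validate a leadfield from the HDF5 container.

    Raises
    ------
    ValueError
        If shapes are inconsistent or an average-referenced gain has
        non-zero column sums.
    """
    with h5py.File(path, "r") as f:
        if "gain" not in f or "grid" not in f:
            raise ValueError("leadfield container must hold /gain and /grid")
        gain = f["gain"][()]
        grid = f["grid"][()]
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f["channel_names"][()]
        ]
        return Leadfield(
            gain=gain,
            grid=grid,
            spacing_mm=float(f.attrs["spacing_mm"]),
            conductivities=tuple(f.attrs["conductivities"]),
            channel_names=names,
            shell_radii_mm=tuple(f.attrs["shell_radii_mm"]),
            reference_scheme=str(f.attrs["reference"]),
        )
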