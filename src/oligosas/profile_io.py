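"""Reading, validation and writing of 1-D scattering profiles.

A profile is the reduced, buffer-subtracted small-angle scattering curve
I(Q) vs the wave vector transfer Q = 4*pi*sin(theta)/lambda (2*theta the
scattering angle, lambda the wavelength), with per-point uncertainties.
Files are plain 3-column whitespace-delimited ASCII (Q [1/A], I, sigma),
'#' comment lines allowed — the de-facto ``.dat`` exchange format of the
SAXS community.

Q is always in inverse Angstrom. Files recorded in inverse nanometre must
be converted explicitly by the caller (multiply Q by 0.1); no unit guessing
is performed, because a silently mis-detected unit shifts Rg by a factor 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MIN_POINTS = 10


class ProfileError(ValueError):
    """Raised for malformed or invalid scattering-profile input."""


@dataclass
class ScatteringProfile:
    """A 1-D scattering curve (Q, I(Q), sigma(Q)).

    Attributes
    ----------
    q : ndarray
        Momentum transfer, 1/A, strictly increasing, q[0] > 0.
    intensity : ndarray
        Scattered intensity, arbitrary units. May contain non-positive
        values (legitimate after buffer subtraction); downstream fits
        select the usable points themselves.
    sigma : ndarray
        Per-point intensity uncertainty, same units, strictly positive.
    label : str
        Free-text sample label.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.q.size
        if not (self.intensity.size == n and self.sigma.size == n):
            raise ProfileError("q, intensity and sigma must have equal length")
        if n < MIN_POINTS:
            raise ProfileError(f"profile needs >= {MIN_POINTS} points, got {n}")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)) \
                or not np.all(np.isfinite(self.sigma)):
            raise ProfileError("profile contains non-finite values")
        if self.q[0] <= 0:
            raise ProfileError("q must be positive (q[0] <= 0)")
        if np.any(np.diff(self.q) <= 0):
            raise ProfileError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ProfileError("sigma must be strictly positive everywhere")

    def __len__(self) -> int:
        return self.q.size

    def with_label(self, label: str) -> "ScatteringProfile":
        return replace(self, label=label)


def read_profile(path: str | Path, dialect: str = "plain3col") -> ScatteringProfile:
    """Read a 3-column ASCII ``.dat`` profile.

    Comment lines starting with '#' are skipped; rows containing
    non-finite values (``nan``/``inf``) are dropped with a logged count.
    2-column files (no sigma) are rejected: every downstream fit here is
    uncertainty-weighted.

    Raises
    ------
    ProfileError
        On malformed rows (with the offending line number), fewer than 10
        valid rows, or a non-increasing Q grid.
    """
    if dialect != "plain3col":
        raise ProfileError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise ProfileError(f"no such file: {path}")

    rows: list[tuple[float, float, float]] = []
    n_dropped = 0
    label = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if stripped.startswith("# label:"):
                    label = stripped[len("# label:"):].strip() or label
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ProfileError(
                    f"{path}:{lineno}: expected 3 columns (Q I sigma), got {len(parts)}"
                )
            try:
                q, i, s = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ProfileError(f"{path}:{lineno}: unparseable value ({exc})") from exc
            if not (np.isfinite(q) and np.isfinite(i) and np.isfinite(s)):
                n_dropped += 1
                continue
            rows.append((q, i, s))

    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite values", path, n_dropped)
    if len(rows) < MIN_POINTS:
        raise ProfileError(f"{path}: only {len(rows)} valid rows (need >= {MIN_POINTS})")

    arr = np.array(rows, dtype=float)
    return ScatteringProfile(q=arr[:, 0], intensity=arr[:, 1], sigma=arr[:, 2], label=label)


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    """Write a profile as 3-column ASCII with a '#' header.

    Values are printed with 17 significant digits so that a read/write
    round trip reproduces the profile exactly and a second write of the
    re-read file is byte-identical.
    """
    path = Path(path)
    label = profile.label or "(unlabelled)"
    lines = [
        f"# label: {label}",
        "# Q(1/A)  I(arb)  sigma(arb)",
    ]
    for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
        lines.append(f"{q:.17g} {i:.17g} {s:.17g}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write profile to {path}: {exc}") from exc


def rebin_to_grid(profile: ScatteringProfile, target_q: np.ndarray) -> ScatteringProfile:
    """Linearly interpolate a profile onto ``target_q``.

    Sigma is interpolated the same way as intensity — a documented
    simplification (no error propagation across bins); adequate for
    placing model and experimental curves on a common grid.
    """
    target_q = np.asarray(target_q, dtype=float)
    if target_q[0] < profile.q[0] or target_q[-1] > profile.q[-1]:
        raise ProfileError(
            f"target grid [{target_q[0]:g}, {target_q[-1]:g}] outside data range "
            f"[{profile.q[0]:g}, {profile.q[-1]:g}]"
        )
    return ScatteringProfile(
        q=target_q,
        intensity=np.interp(target_q, profile.q, profile.intensity),
        sigma=np.interp(target_q, profile.q, profile.sigma),
        label=profile.label,
    )


def default_q_grid(qmin: float = 0.008, qmax: float = 0.35, n: int = 150) -> np.ndarray:
    """Log-spaced default Q grid, 1/A (an artifact choice; the instrument
    binning is not part of the model)."""
    return np.geomspace(qmin, qmax, n)
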