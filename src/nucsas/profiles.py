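"""One-dimensional scattering profiles and their experiment metadata.

The on-disk dialect is the de-facto SAS convention: whitespace-separated
3-column ASCII (q, I, sigma) with ``#``-prefixed header lines.  Header lines
of the form ``# key = value`` carry experiment metadata and survive a
read/write round trip.  q is in inverse Angstroms everywhere; files declaring
``q_units = nm^-1`` in their header are converted on read.

Numeric output uses ``%.17e`` (17 significant digits), enough for every
IEEE-754 double to round-trip bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ScatteringProfile",
    "ProfileFormatError",
    "read_profile",
    "write_profile",
    "trim_and_merge",
    "read_manifest",
    "write_manifest",
]

#: fraction of I(q) used to impute sigma for 2-column files
SIGMA_IMPUTE_FRACTION = 0.02

_META_FLOATS = ("fraction_d2o", "concentration", "pressure", "temperature")
_META_BOOLS = ("absolute_scale", "sigma_imputed")


class ProfileFormatError(ValueError):
    """Raised when a .dat file violates the 3-column profile contract."""


@dataclass
class ScatteringProfile:
    """A single 1-D scattering curve with experiment metadata.

    Parameters
    ----------
    q : array
        Momentum transfer, 1/Angstrom, strictly increasing and positive.
    intensity : array
        I(q); cm^-1 when ``meta['absolute_scale']`` is true, else arbitrary.
    sigma : array
        1-standard-deviation uncertainty on I(q), same units, > 0.
    meta : dict
        Keys used by the package: ``source`` ('xray' or 'neutron'),
        ``fraction_d2o`` (0-1), ``concentration`` (mg/mL), ``pressure``
        (MPa), ``temperature`` (deg C), ``absolute_scale`` (bool),
        ``label`` (free text).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    def validate(self):
        if not (self.q.shape == self.intensity.shape == self.sigma.shape):
            raise ProfileFormatError("q, intensity, sigma must have equal length")
        if self.q.ndim != 1 or self.q.size < 8:
            raise ProfileFormatError("profile needs >= 8 points")
        if not np.all(self.q > 0):
            row = int(np.argmax(self.q <= 0))
            raise ProfileFormatError(f"non-positive q at row {row}")
        dq = np.diff(self.q)
        if not np.all(dq > 0):
            row = int(np.argmax(dq <= 0)) + 1
            raise ProfileFormatError(f"q not strictly increasing at row {row}")
        if not np.all(self.sigma > 0):
            row = int(np.argmax(self.sigma <= 0))
            raise ProfileFormatError(f"non-positive sigma at row {row}")
        f = self.meta.get("fraction_d2o")
        if f is not None and not (0.0 <= float(f) <= 1.0):
            raise ProfileFormatError(f"fraction_d2o {f} outside [0, 1]")
        p = self.meta.get("pressure")
        if p is not None and float(p) < 0:
            raise ProfileFormatError(f"negative pressure {p}")

    @property
    def n_points(self) -> int:
        return self.q.size

    def copy(self) -> "ScatteringProfile":
        return ScatteringProfile(
            self.q.copy(), self.intensity.copy(), self.sigma.copy(), dict(self.meta)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScatteringProfile):
            return NotImplemented
        return (
            np.array_equal(self.q, other.q)
            and np.array_equal(self.intensity, other.intensity)
            and np.array_equal(self.sigma, other.sigma)
            and self.meta == other.meta
        )


def _parse_meta_value(key: str, raw: str):
    raw = raw.strip()
    if key in _META_BOOLS:
        return raw.lower() in ("1", "true", "yes")
    if key in _META_FLOATS:
        return float(raw)
    return raw


def read_profile(path, dialect: str = "ascii3col") -> ScatteringProfile:
    """Read a 3-column (or 2-column) ASCII .dat profile.

    Header lines start with ``#``; ``# key = value`` lines populate
    ``profile.meta``.  2-column files get sigma imputed as
    ``SIGMA_IMPUTE_FRACTION * |I|`` and ``meta['sigma_imputed'] = True``.
    """
    if dialect != "ascii3col":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    rows = []
    ncols = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key:
                    meta[key] = _parse_meta_value(key, val)
            continue
        parts = s.split()
        if len(parts) not in (2, 3):
            raise ProfileFormatError(
                f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise ProfileFormatError(f"{path}:{lineno}: non-numeric value") from exc
        if ncols is None:
            ncols = len(parts)
        elif len(parts) != ncols:
            raise ProfileFormatError(f"{path}:{lineno}: inconsistent column count")
        rows.append(vals)
    if not rows:
        raise ProfileFormatError(f"{path}: empty profile")
    if len(rows) < 8:
        raise ProfileFormatError(f"{path}: fewer than 8 data rows")
    arr = np.array(rows, dtype=float)
    q = arr[:, 0]
    intensity = arr[:, 1]
    if meta.get("q_units", "").replace("^", "") in ("nm-1", "1/nm"):
        q = q / 10.0  # nm^-1 -> A^-1
        meta.pop("q_units")
    if ncols == 3:
        sigma = arr[:, 2]
    else:
        sigma = SIGMA_IMPUTE_FRACTION * np.abs(intensity)
        sigma[sigma == 0] = SIGMA_IMPUTE_FRACTION * max(np.abs(intensity).max(), 1.0)
        meta["sigma_imputed"] = True
    try:
        return ScatteringProfile(q, intensity, sigma, meta)
    except ProfileFormatError as exc:
        raise ProfileFormatError(f"{path}: {exc}") from exc


def write_profile(profile: ScatteringProfile, path) -> Path:
    """Write ``profile`` as 3-column ASCII with a full metadata header."""
    if not str(path):
        raise ValueError("empty output path")
    path = Path(path)
    lines = ["# nucsas 1-D scattering profile"]
    units = "cm^-1" if profile.meta.get("absolute_scale") else "arbitrary"
    lines.append(f"# columns: q(A^-1) I({units}) sigma({units})")
    for key in sorted(profile.meta):
        lines.append(f"# {key} = {profile.meta[key]}")
    for qi, ii, si in zip(profile.q, profile.intensity, profile.sigma):
        lines.append(f"{qi:.17e} {ii:.17e} {si:.17e}")
    path.write_text("\n".join(lines) + "\n")
    return path


_MERGE_META_KEYS = ("fraction_d2o", "source", "pressure")


def trim_and_merge(profiles, overlap_policy: str = "scale-to-first") -> ScatteringProfile:
    """Merge profiles covering different q ranges into one curve.

    Profiles must describe the same sample: metadata in fraction_d2o /
    source / pressure must agree.  With ``overlap_policy='scale-to-first'``
    each later profile is rescaled to the running merge by weighted least
    squares on the overlap window before being appended; ``'no-scale'``
    appends as-is.  In overlap windows points from all contributing curves
    are kept (interleaved on the union grid); uncertainties are carried
    through (scaled where the intensity is scaled), so the merged sigma is
    never smaller than the smallest input sigma at that q.
    """
    profiles = list(profiles)
    if len(profiles) == 1:
        return profiles[0].copy()
    if not profiles:
        raise ValueError("no profiles to merge")
    if overlap_policy not in ("scale-to-first", "no-scale"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    ref = profiles[0]
    for p in profiles[1:]:
        for key in _MERGE_META_KEYS:
            a, b = ref.meta.get(key), p.meta.get(key)
            if a is not None and b is not None and a != b:
                raise ValueError(f"inconsistent metadata for merge: {key} {a} vs {b}")

    profiles = sorted(profiles, key=lambda p: p.q[0])
    q = ref.q.copy()
    i = ref.intensity.copy()
    s = ref.sigma.copy()
    for p in profiles[1:] if profiles[0] is ref else profiles:
        if p is ref:
            continue
        lo, hi = max(q[0], p.q[0]), min(q[-1], p.q[-1])
        if hi <= lo:
            raise ValueError(
                f"no q overlap between merged range [{q[0]:g}, {q[-1]:g}] "
                f"and profile [{p.q[0]:g}, {p.q[-1]:g}]"
            )
        scale = 1.0
        if overlap_policy == "scale-to-first":
            mask = (p.q >= lo) & (p.q <= hi)
            ref_i = np.interp(p.q[mask], q, i)
            w = 1.0 / p.sigma[mask] ** 2
            denom = np.sum(w * p.intensity[mask] ** 2)
            if denom > 0:
                scale = np.sum(w * ref_i * p.intensity[mask]) / denom
        q = np.concatenate([q, p.q])
        i = np.concatenate([i, scale * p.intensity])
        s = np.concatenate([s, scale * p.sigma])
        order = np.argsort(q, kind="stable")
        q, i, s = q[order], i[order], s[order]
        # collapse exactly duplicated q by inverse-variance weighting;
        # the combined sigma uses the conservative max rule so merging
        # never reports better precision than its best input
        uq, idx = np.unique(q, return_index=True)
        if uq.size != q.size:
            new_i = np.empty_like(uq)
            new_s = np.empty_like(uq)
            for k, qv in enumerate(uq):
                sel = q == qv
                w = 1.0 / s[sel] ** 2
                new_i[k] = np.sum(w * i[sel]) / np.sum(w)
                new_s[k] = np.min(s[sel])
            q, i, s = uq, new_i, new_s
    meta = dict(ref.meta)
    meta["merged"] = True
    return ScatteringProfile(q, i, s, meta)


def write_manifest(entries, path) -> Path:
    """Write a JSON-lines manifest binding .dat paths to metadata."""
    path = Path(path)
    with path.open("w") as fh:
        for entry in entries:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return path


def read_manifest(path):
    """Read a JSON-lines manifest; returns a list of dicts."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(json.loads(line))
    return out
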