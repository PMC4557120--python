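"""Reading, writing and pre-processing of spectro-temporal matrices.

The universal data currency is :class:`SpectroTemporalMatrix`, a rectangular
table of (difference-)absorbance values with explicit time (s) and wavelength
(nm) axes.  This module also implements the streak-camera difference-absorbance
computation, trigger-offset alignment of single-wavelength kinetic traces, and
logarithmic time binning of densely sampled slow kinetics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOWS = ("fs_ns", "ns_us", "ms_s", "steady_state")
KINDS = ("absolute", "difference")

#: sentinel used for masked / unmeasurable pixels
MISSING = np.nan


class ValidationError(ValueError):
    """Raised when a matrix or its axes violate an invariant."""


@dataclass
class SpectroTemporalMatrix:
    """A time x wavelength matrix of absorbance (or ΔA) values.

    Parameters
    ----------
    values
        ``(N_T, N_L)`` array in OD.  Masked pixels hold NaN.
    time_axis
        Strictly increasing times in seconds (or illumination-step index for
        ``steady_state`` series), length ``N_T``.
    wavelength_axis
        Strictly increasing wavelengths in nm, length ``N_L``.
    window
        One of ``fs_ns``, ``ns_us``, ``ms_s``, ``steady_state``.
    kind
        ``absolute`` or ``difference``.
    """

    values: np.ndarray
    time_axis: np.ndarray
    wavelength_axis: np.ndarray
    window: str = "fs_ns"
    kind: str = "difference"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.wavelength_axis = np.asarray(self.wavelength_axis, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.size == 0:
            raise ValidationError("empty matrix")
        n_t, n_l = self.values.shape
        if self.time_axis.shape != (n_t,):
            raise ValidationError(
                f"time axis length {self.time_axis.size} != {n_t} rows"
            )
        if self.wavelength_axis.shape != (n_l,):
            raise ValidationError(
                f"wavelength axis length {self.wavelength_axis.size} != {n_l} columns"
            )
        for name, ax in (("time", self.time_axis), ("wavelength", self.wavelength_axis)):
            if not np.all(np.isfinite(ax)):
                raise ValidationError(f"{name} axis contains non-finite entries")
            if np.any(np.diff(ax) <= 0):
                bad = int(np.argmax(np.diff(ax) <= 0))
                raise ValidationError(
                    f"{name} axis not strictly increasing at index {bad} "
                    f"(value {ax[bad + 1]!r} follows {ax[bad]!r})"
                )
        if np.any(np.isinf(self.values)):
            raise ValidationError("values contain infinities")
        if self.window not in WINDOWS:
            raise ValidationError(f"unknown window {self.window!r}")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class RawStreakFrames:
    """The four detector frames of one streak-camera acquisition sequence.

    ``d_fl``: flash lamp + laser; ``d_0``/``d_0_repeat``: dark frames recorded
    before and after; ``d_f``: flash lamp only.  All counts.
    """

    d_fl: np.ndarray
    d_0: np.ndarray
    d_f: np.ndarray
    d_0_repeat: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in
                (self.d_fl, self.d_0, self.d_f, self.d_0_repeat)]
        self.d_fl, self.d_0, self.d_f, self.d_0_repeat = arrs
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValidationError(f"frame shapes differ: {sorted(shapes)}")


def write_matrix(m: SpectroTemporalMatrix, path) -> None:
    """Write a matrix as delimited text, re-readable by :func:`read_matrix`.

    Layout: '#'-prefixed metadata header, then a header row of wavelengths and
    one row per time point with the time in the first column.
    """
    header = [
        "# photokin spectro-temporal matrix",
        f"# window: {m.window}",
        f"# kind: {m.kind}",
        f"# meta: {json.dumps(m.meta, default=str)}",
    ]
    cols = ",".join(repr(float(w)) for w in m.wavelength_axis)
    lines = header + [f"time_s,{cols}"]
    for t, row in zip(m.time_axis, m.values):
        lines.append(",".join([repr(float(t))] + [repr(float(v)) for v in row]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_matrix(path, sep: str = ",") -> SpectroTemporalMatrix:
    """Read a delimited-text spectro-temporal matrix.

    First non-comment row holds wavelengths (nm), first column holds times (s).
    '#'-prefixed lines carry ``window``, ``kind`` and ``meta`` metadata.
    """
    window, kind, meta = "fs_ns", "difference", {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if body.startswith("window:"):
            window = body.split(":", 1)[1].strip()
        elif body.startswith("kind:"):
            kind = body.split(":", 1)[1].strip()
        elif body.startswith("meta:"):
            try:
                meta = json.loads(body.split(":", 1)[1].strip())
            except json.JSONDecodeError:
                meta = {}
    from io import StringIO

    try:
        df = pd.read_csv(StringIO(text), comment="#", sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"malformed table in {path}: {exc}") from exc
    try:
        wl = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"header row of {path} is not numeric wavelengths: {exc}"
        ) from exc
    if len(set(df.columns)) != len(df.columns):
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValidationError(f"duplicated wavelength column(s): {dupes}")
    times = df.index.to_numpy(dtype=float)
    return SpectroTemporalMatrix(df.to_numpy(dtype=float), times, wl,
                                 window=window, kind=kind, meta=meta)


def compute_streak_delta_a(
    frames: RawStreakFrames,
    time_axis=None,
    wavelength_axis=None,
    mask=None,
    window: str = "ns_us",
) -> SpectroTemporalMatrix:
    """ΔA = −log10((D_FL − D_0) / (D_F − D_0)) with the two dark frames averaged.

    Pixels with a non-positive numerator or denominator (no transmitted light)
    are set to the missing sentinel and counted in the log; an entirely masked
    matrix is an error.  ``mask`` marks pixels expected to be unusable; masked
    pixels outside it are reported as a warning count.
    """
    d0 = 0.5 * (frames.d_0 + frames.d_0_repeat)
    num = frames.d_fl - d0
    den = frames.d_f - d0
    bad = (num <= 0) | (den <= 0)
    out = np.full(num.shape, MISSING)
    ok = ~bad
    out[ok] = -np.log10(num[ok] / den[ok])
    if mask is None:
        mask = np.zeros(num.shape, dtype=bool)
    unexpected = bad & ~np.asarray(mask, dtype=bool)
    if unexpected.any():
        logger.warning("streak ΔA: %d unexpected non-positive pixels masked",
                       int(unexpected.sum()))
    if bad.all():
        raise ValidationError("all pixels masked: no usable streak signal")
    n_t, n_l = out.shape
    if time_axis is None:
        time_axis = np.arange(n_t, dtype=float)
    if wavelength_axis is None:
        wavelength_axis = np.arange(n_l, dtype=float)
    return SpectroTemporalMatrix(
        out, time_axis, wavelength_axis, window=window, kind="difference",
        meta={"masked_pixels": int(bad.sum())},
    )


def align_t0(
    traces,
    t0_estimates,
    wavelengths,
    window: str = "ms_s",
    kind: str = "difference",
) -> SpectroTemporalMatrix:
    """Assemble single-wavelength traces onto a common time axis with t=0 at
    excitation.

    Parameters
    ----------
    traces
        Sequence of ``(time_axis, values)`` pairs, one per wavelength; each
        trace carries its own trigger offset.
    t0_estimates
        Per-trace trigger time (s); subtracted before interpolation.
    wavelengths
        Wavelength (nm) per trace; must be strictly increasing and match the
        trace count.
    """
    traces = list(traces)
    t0_estimates = np.asarray(t0_estimates, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not (len(traces) == t0_estimates.size == wavelengths.size):
        raise ValidationError(
            f"got {len(traces)} traces, {t0_estimates.size} offsets, "
            f"{wavelengths.size} wavelengths; counts must match"
        )
    shifted = []
    for (t, v), t0 in zip(traces, t0_estimates):
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        span = t[-1] - t[0]
        if abs(t0) >= span:
            raise ValidationError(
                f"trigger offset {t0} exceeds trace span {span}"
            )
        shifted.append((t - t0, v))
    lo = max(t[0] for t, _ in shifted)
    hi = min(t[-1] for t, _ in shifted)
    if hi <= lo:
        raise ValidationError("traces share no common time range after alignment")
    base = shifted[0][0]
    grid = base[(base >= lo) & (base <= hi)]
    cols = [np.interp(grid, t, v) for t, v in shifted]
    return SpectroTemporalMatrix(
        np.column_stack(cols), grid, wavelengths, window=window, kind=kind,
        meta={"t0_alignment": "linear interpolation onto first-trace grid"},
    )


def log_time_bin(m: SpectroTemporalMatrix, n_out: int) -> SpectroTemporalMatrix:
    """Average rows into ``n_out`` logarithmically equally spaced time bins.

    Bin edges span the first positive time to the last time; each output value
    is the arithmetic mean of its bin members; empty bins are dropped.  Rows at
    t <= 0 are discarded (a logarithmic axis cannot hold them).
    """
    if n_out >= m.n_times:
        raise ValidationError(
            f"n_out={n_out} >= N_T={m.n_times}: binning would be a no-op"
        )
    if n_out < 1:
        raise ValidationError("n_out must be positive")
    pos = m.time_axis > 0
    if not pos.any():
        raise ValidationError("no positive times to bin")
    t = m.time_axis[pos]
    v = m.values[pos]
    edges = np.geomspace(t[0], t[-1], n_out + 1)
    # right-inclusive last bin so the final point is kept
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_out - 1)
    t_out, v_out = [], []
    for b in range(n_out):
        sel = idx == b
        if not sel.any():
            continue
        t_out.append(t[sel].mean())
        v_out.append(v[sel].mean(axis=0))
    return SpectroTemporalMatrix(
        np.asarray(v_out), np.asarray(t_out), m.wavelength_axis,
        window=m.window, kind=m.kind,
        meta={**m.meta, "log_binned_from": m.n_times},
    )
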