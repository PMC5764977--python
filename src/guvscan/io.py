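"""File formats: Touchstone .s2p spectra, CSV spectra and CSV scan traces.

Spectra are written as standard 2-port Touchstone (frequency in Hz, RI
format, 50-ohm reference) and as a CSV mirror with columns
``freq_hz, re_s21, im_s21, re_s11, im_s11``.  Scan traces use the dialect
``time_s, re_s21, im_s21`` with a header row, UTF-8.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circuit import S21Spectrum
from .errors import InputError
from .traces import ScanTrace

# ---------------------------------------------------------------------------
# Touchstone two-port
# ---------------------------------------------------------------------------


def write_s2p(path, spectrum: S21Spectrum, z0: float = 50.0) -> None:
    """Write a two-port Touchstone file (HZ / S / RI), column order
    S11 S21 S12 S22; the network is reciprocal and symmetric so S12 = S21 and
    S22 = S11."""
    spectrum.validate(passive=False)
    s11 = spectrum.s11 if spectrum.s11 is not None else np.zeros_like(spectrum.s21)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in spectrum.metadata.items():
            fh.write(f"! {key}: {value}\n")
        fh.write(f"# HZ S RI R {z0:g}\n")
        for f, a, b in zip(spectrum.frequency_hz, s11, spectrum.s21):
            fh.write(
                f"{f:.10e} {a.real:.12e} {a.imag:.12e} {b.real:.12e} {b.imag:.12e} "
                f"{b.real:.12e} {b.imag:.12e} {a.real:.12e} {a.imag:.12e}\n"
            )


def read_s2p(path) -> S21Spectrum:
    """Read a 2-port Touchstone file written in HZ / S / RI format."""
    meta, rows = {}, []
    unit_scale = 1.0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("!"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("#"):
                tokens = line[1:].upper().split()
                unit_scale = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}.get(tokens[0], 1.0)
                if "S" not in tokens or "RI" not in tokens:
                    raise InputError("only S-parameter RI Touchstone files are supported")
                continue
            rows.append([float(v) for v in line.split()])
    if not rows:
        raise InputError(f"no data rows in {path}")
    arr = np.asarray(rows)
    if arr.shape[1] != 9:
        raise InputError("expected a 2-port Touchstone file with 9 columns")
    return S21Spectrum(
        frequency_hz=arr[:, 0] * unit_scale,
        s11=arr[:, 1] + 1j * arr[:, 2],
        s21=arr[:, 3] + 1j * arr[:, 4],
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# CSV mirrors
# ---------------------------------------------------------------------------


def write_spectrum_csv(path, spectrum: S21Spectrum) -> None:
    s11 = spectrum.s11 if spectrum.s11 is not None else np.zeros_like(spectrum.s21)
    pd.DataFrame(
        {
            "freq_hz": spectrum.frequency_hz,
            "re_s21": np.real(spectrum.s21),
            "im_s21": np.imag(spectrum.s21),
            "re_s11": np.real(s11),
            "im_s11": np.imag(s11),
        }
    ).to_csv(path, index=False)


def read_spectrum_csv(path) -> S21Spectrum:
    df = pd.read_csv(path)
    return S21Spectrum(
        frequency_hz=df["freq_hz"].to_numpy(),
        s21=df["re_s21"].to_numpy() + 1j * df["im_s21"].to_numpy(),
        s11=(df["re_s11"].to_numpy() + 1j * df["im_s11"].to_numpy()) if "re_s11" in df else None,
    )


def write_trace(path, trace: ScanTrace) -> None:
    """Scan-trace CSV: columns time_s, re_s21, im_s21 (header required)."""
    trace.validate()
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "re_s21": np.real(trace.s21),
            "im_s21": np.imag(trace.s21),
        }
    ).to_csv(path, index=False)


def read_trace(path, frequency_hz: float = 0.0, metadata: dict | None = None) -> ScanTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "re_s21", "im_s21"):
        if col not in df:
            raise InputError(f"trace CSV must contain column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise InputError("trace CSV needs at least two samples")
    trace = ScanTrace(
        time_s=t,
        s21=df["re_s21"].to_numpy() + 1j * df["im_s21"].to_numpy(),
        frequency_hz=frequency_hz,
        sample_rate_hz=1.0 / (t[1] - t[0]),
        metadata=dict(metadata or {}),
    )
    trace.validate()
    return trace


def write_fieldmap_csv(path, fmap) -> None:
    """Cell-centred field map as CSV: x, y, |E|^2 components and potential of
    the nearest node grid are exported at cell centres."""
    xc, yc = fmap.xc, fmap.yc
    xx, yy = np.meshgrid(xc, yc)
    phi_c = 0.25 * (
        fmap.phi[:-1, :-1] + fmap.phi[1:, :-1] + fmap.phi[:-1, 1:] + fmap.phi[1:, 1:]
    )
    pd.DataFrame(
        {
            "x_m": xx.ravel(),
            "y_m": yy.ravel(),
            "phi_v": np.real(phi_c).ravel(),
            "ex_v_per_m": np.real(fmap.ex).ravel(),
            "ey_v_per_m": np.real(fmap.ey).ravel(),
        }
    ).to_csv(path, index=False)
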