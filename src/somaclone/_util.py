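"""Shared plumbing: errors, deterministic RNG sub-streams, rounding conventions."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
BASE_CODES = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


class SomacloneError(Exception):
    """Base class for package errors."""


class ParseError(SomacloneError):
    """Malformed input file; message carries file and line context."""


class PipelineError(SomacloneError):
    """A stage was run without its upstream dependency."""


def substream(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a run seed and a label.

    One seeded generator per run; sub-streams are keyed by stage name so a
    stage can be re-run in isolation and see the same draws.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for all printed percentages)."""
    factor = 10.0**decimals
    scaled = x * factor
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with the package-wide rounding convention.

    >>> percent(2612, 3037)
    86.0
    """
    if denominator == 0:
        return 0.0
    return float(round_half_away(100.0 * numerator / denominator, decimals))


def encode_seq(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.uint8)
    for base, code in BASE_CODES.items():
        out[arr == ord(base)] = code
    return out


def decode_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()
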