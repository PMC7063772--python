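"""Windowed local folding energy (LFE) profiles.

Local folding energy of an mRNA window is the minimum free energy over
secondary structures of that window; profiles slide a 40-nt window in
10-nt steps along the CDS, anchored either at the CDS start or end.

The default energy backend is a deterministic nested-pairing dynamic
program with fixed integer pair energies (GC = -3, AU = -2, GU = -1,
hairpin loops of at least 3 unpaired bases).  These constants are NOT
thermodynamic: the backend is a fast, dependency-free stand-in whose
only job is to score base-pairing potential reproducibly.  An adapter
for RNAfold-compatible programs is provided for users who want real
minimum free energies in kcal/mol.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "LFEProfile",
    "fold_energy_builtin",
    "fold_energies_builtin",
    "fold_energy_exhaustive",
    "lfe_profile",
    "window_offsets",
    "BuiltinBackend",
    "RNAfoldBackend",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
    "DEFAULT_MAX_SPAN",
]

DEFAULT_WINDOW = 40
DEFAULT_STEP = 10
DEFAULT_MAX_SPAN = 300

# base encoding: A=0, C=1, G=2, U/T=3
_BASE_CODE = np.full(128, -1, dtype=np.int8)
for _b, _c in (("A", 0), ("C", 1), ("G", 2), ("T", 3), ("U", 3)):
    _BASE_CODE[ord(_b)] = _c
    _BASE_CODE[ord(_b.lower())] = _c

# pair energy lookup, indexed [b1, b2]
_PAIR_E = np.zeros((4, 4), dtype=np.float64)
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3.0  # G:C
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2.0  # A:U
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1.0  # G:U


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/U string (case-insensitive) as int8 codes."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGTU character {bad!r} in sequence")
    return arr


@njit(cache=True)
def _fold_one(codes, pair_e, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    E = np.zeros((n + 1, n + 1), dtype=np.float64)
    # E[i, j] = min energy of subsequence codes[i:j] (half-open), 0 if empty
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = E[i + 1, j]  # i unpaired
            ci = codes[i]
            for k in range(i + min_loop + 1, j):
                e = pair_e[ci, codes[k]]
                if e < 0.0:
                    cand = e + E[i + 1, k] + E[k + 1, j]
                    if cand < best:
                        best = cand
            E[i, j] = best
    return E[0, n]


@njit(cache=True)
def _fold_many(codes2d, pair_e, min_loop):  # pragma: no cover - jitted
    m = codes2d.shape[0]
    out = np.empty(m, dtype=np.float64)
    for w in range(m):
        out[w] = _fold_one(codes2d[w], pair_e, min_loop)
    return out


def fold_energy_builtin(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over nested secondary structures of ``seq``.

    Pair energies GC=-3, AU=-2, GU=-1; a pair (i, k) requires at least
    ``min_loop`` bases between i and k.  Returns 0.0 when no pairing
    improves on the open chain; never positive.
    """
    if not seq:
        raise ValueError("empty sequence")
    return float(_fold_one(encode_seq(seq), _PAIR_E, min_loop))


def fold_energies_builtin(windows: np.ndarray, min_loop: int = 3) -> np.ndarray:
    """Fold a batch of equal-length encoded windows (2-D int8 array)."""
    if windows.ndim != 2:
        raise ValueError("expected a 2-D array of encoded windows")
    if windows.shape[0] == 0:
        return np.empty(0, dtype=np.float64)
    return _fold_many(np.ascontiguousarray(windows), _PAIR_E, min_loop)


def fold_energy_exhaustive(seq: str, min_loop: int = 3) -> float:
    """Exhaustive-enumeration oracle for the builtin energy model.

    Recursively enumerates every pseudoknot-free pairing (no memoised
    recurrence is shared with the DP) and returns the minimum total
    energy.  Exponential: intended for sequences of ~25 nt or less.
    """
    codes = encode_seq(seq)

    def best(i: int, j: int) -> float:
        # min energy of codes[i:j]; plain recursion, no memo
        if j - i < min_loop + 2:
            return 0.0
        b = best(i + 1, j)
        for k in range(i + min_loop + 1, j):
            e = _PAIR_E[codes[i], codes[k]]
            if e < 0.0:
                cand = e + best(i + 1, k) + best(k + 1, j)
                if cand < b:
                    b = cand
        return b

    return float(best(0, len(codes)))


@dataclass
class LFEProfile:
    """Per-window folding energies for one sequence and one anchor.

    ``positions`` are window offsets in nt: for the start anchor, the
    offset of the window's first base from the CDS start; for the end
    anchor, the offset of the window's last base from the CDS end (so
    offset 0 is the window covering the final 40 nt).
    """

    anchor: str
    window_size: int
    step: int
    positions: np.ndarray
    energies: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


def window_offsets(length: int, window_size: int = DEFAULT_WINDOW,
                   step: int = DEFAULT_STEP,
                   max_span: int = DEFAULT_MAX_SPAN) -> np.ndarray:
    """Grid of window offsets for a sequence of ``length`` nt."""
    if length < window_size:
        return np.empty(0, dtype=np.int64)
    last = min(max_span, length - window_size)
    return np.arange(0, last + 1, step, dtype=np.int64)


def window_slices(length: int, anchor: str, window_size: int = DEFAULT_WINDOW,
                  step: int = DEFAULT_STEP,
                  max_span: int = DEFAULT_MAX_SPAN) -> tuple[np.ndarray, np.ndarray]:
    """(offsets, window start indices) for a sequence of ``length``.

    End-anchored windows END ``offset`` nt before the 3' terminus:
    offset e covers [length - window_size - e, length - e).
    """
    offs = window_offsets(length, window_size, step, max_span)
    if anchor == "start":
        starts = offs.copy()
    elif anchor == "end":
        starts = length - window_size - offs
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return offs, starts


class BuiltinBackend:
    """Deterministic nested-pairing DP backend (arbitrary energy units)."""

    name = "builtin"

    def __init__(self, min_loop: int = 3, temperature: float = 37.0):
        # temperature accepted for interface parity; the toy energy
        # model has no temperature dependence.
        self.min_loop = min_loop
        self.temperature = temperature

    def fold_many(self, windows: np.ndarray) -> np.ndarray:
        return fold_energies_builtin(windows, self.min_loop)

    def fold(self, seq: str) -> float:
        return fold_energy_builtin(seq, self.min_loop)


class RNAfoldBackend:
    """Adapter for RNAfold-compatible MFE programs (kcal/mol).

    Feeds sequences on stdin, one per line, and parses the trailing
    "( energy )" of each structure line.  Requires the external binary
    on PATH; this backend is opt-in and never used by default.
    """

    name = "rnafold"

    def __init__(self, program: str = "RNAfold", temperature: float = 37.0):
        if shutil.which(program) is None:
            raise RuntimeError(f"{program} not found on PATH")
        self.program = program
        self.temperature = temperature

    def fold(self, seq: str) -> float:
        return self.fold_seqs([seq])[0]

    def fold_seqs(self, seqs: Sequence[str]) -> list[float]:
        inp = "\n".join(s.replace("T", "U").replace("t", "u") for s in seqs)
        proc = subprocess.run(
            [self.program, "--noPS", "-T", str(self.temperature)],
            input=inp, capture_output=True, text=True, check=True)
        energies = []
        for line in proc.stdout.splitlines():
            line = line.strip()
            if line and (line[0] in ".()" ) and line.endswith(")"):
                energies.append(float(line[line.rfind("(") + 1:-1]))
        if len(energies) != len(seqs):
            raise RuntimeError("could not parse one energy per input sequence")
        return energies

    def fold_many(self, windows: np.ndarray) -> np.ndarray:
        decode = np.array(list("ACGU"))
        seqs = ["".join(decode[w]) for w in windows]
        return np.asarray(self.fold_seqs(seqs), dtype=np.float64)


class EnergyCache:
    """Content-addressed cache of window energies for one backend."""

    def __init__(self, backend):
        self.backend = backend
        self._store: dict[bytes, float] = {}
        self.hits = 0
        self.misses = 0

    def fold_many(self, windows: np.ndarray) -> np.ndarray:
        if windows.shape[0] == 0:
            return np.empty(0)
        keys = [w.tobytes() for w in windows]
        out = np.empty(len(keys), dtype=np.float64)
        miss_idx = [i for i, k in enumerate(keys) if k not in self._store]
        hit_idx = [i for i, k in enumerate(keys) if k in self._store]
        for i in hit_idx:
            out[i] = self._store[keys[i]]
        self.hits += len(hit_idx)
        if miss_idx:
            vals = self.backend.fold_many(windows[miss_idx])
            for j, i in enumerate(miss_idx):
                self._store[keys[i]] = vals[j]
                out[i] = vals[j]
            self.misses += len(miss_idx)
        return out


def lfe_profile(seq: str, anchor: str = "start",
                window_size: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
                max_span: int = DEFAULT_MAX_SPAN,
                backend=None) -> LFEProfile:
    """Windowed folding-energy profile of one sequence.

    Start anchor: windows begin at offsets 0, 10, ..., min(max_span,
    L - window_size).  End anchor: windows end at the same offsets
    measured from the 3' terminus.  A sequence shorter than one window
    yields an empty profile (not an error).
    """
    if backend is None:
        backend = BuiltinBackend()
    offs, starts = window_slices(len(seq), anchor, window_size, step, max_span)
    if len(offs) == 0:
        return LFEProfile(anchor, window_size, step, offs,
                          np.empty(0, dtype=np.float64))
    codes = encode_seq(seq)
    windows = np.stack([codes[s:s + window_size] for s in starts])
    energies = backend.fold_many(windows)
    return LFEProfile(anchor, window_size, step, offs, energies)
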