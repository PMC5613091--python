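"""Nucleotide-composition analysis: windowed G+C content and skew, cumulative
skew, replication-landmark (ori/ter) prediction and in-silico ligation.

On circular bacterial replicons the leading strand is G-rich, so the per-base
skew contribution (+1 for G, -1 for C) accumulates from the origin of
replication to the terminus: the cumulative-skew minimum marks ori and the
maximum marks ter.  For circular molecules prediction uses the detrended
cumulative skew (C_i - i*C_L/L), which makes the extremum positions exactly
equivariant under rotation even when the total G-C of the molecule is nonzero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .genome_io import GeneFeature, Replicon

logger = logging.getLogger(__name__)


@dataclass
class WindowProfile:
    replicon_id: str
    window: int
    step: int
    centers: np.ndarray  # window midpoints, 1-based; unwrapped (monotone)
    values: np.ndarray   # NaN where undefined (all-N windows etc.)
    statistic: str       # gc_content | gc_skew
    mean: float = float("nan")

    @property
    def deviation_from_mean(self) -> np.ndarray:
        return self.values - self.mean


@dataclass
class CumulativeSkewProfile:
    replicon_id: str
    positions: np.ndarray  # 0..L (bases completed)
    values: np.ndarray     # running sum of +1 per G, -1 per C


@dataclass
class OriTerPrediction:
    replicon_id: str
    ori_position: int
    ter_position: int
    method: str
    confidence_note: str = ""


def _base_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_g = arr == ord("G")
    is_c = arr == ord("C")
    is_n = arr == ord("N")
    return is_g, is_c, is_n


def _window_sums(x: np.ndarray, window: int, step: int, circular: bool) -> np.ndarray:
    """Sum of x over each window start (1, 1+step, ...); wraps when circular."""
    n = len(x)
    if circular:
        ext = np.concatenate([x, x[: window - 1]])
        starts = np.arange(0, n, step)
    else:
        starts = np.arange(0, n - window + 1, step)
        ext = x
    cs = np.concatenate([[0], np.cumsum(ext)])
    return cs[starts + window] - cs[starts]


def windowed_gc_content(replicon: Replicon, window: int = 1000,
                        step: Optional[int] = None) -> WindowProfile:
    """(G+C)/(A+C+G+T) per sliding window; Ns excluded from both numerator and
    denominator, all-N windows reported missing (NaN)."""
    if window > replicon.length:
        raise ValueError(f"window {window} exceeds replicon length {replicon.length}")
    step = step or max(1, window // 10)
    circular = replicon.topology == "circular"
    is_g, is_c, is_n = _base_arrays(replicon.sequence)
    gc = _window_sums((is_g | is_c).astype(np.int64), window, step, circular)
    denom = window - _window_sums(is_n.astype(np.int64), window, step, circular)
    values = np.full(len(gc), np.nan)
    ok = denom > 0
    values[ok] = gc[ok] / denom[ok]
    if (~ok).any():
        logger.warning("%s: %d all-N window(s) reported missing", replicon.id, (~ok).sum())
    centers = np.arange(0, len(values)) * step + 1 + window // 2
    n_valid = (~is_n).sum()
    mean = float((is_g | is_c).sum() / n_valid) if n_valid else float("nan")
    return WindowProfile(replicon.id, window, step, centers, values, "gc_content", mean)


def windowed_gc_skew(replicon: Replicon, window: int = 10000,
                     step: Optional[int] = None) -> WindowProfile:
    """(G-C)/(G+C) per sliding window; windows without G or C are missing."""
    if window > replicon.length:
        raise ValueError(f"window {window} exceeds replicon length {replicon.length}")
    step = step or max(1, window // 10)
    circular = replicon.topology == "circular"
    is_g, is_c, _ = _base_arrays(replicon.sequence)
    g = _window_sums(is_g.astype(np.int64), window, step, circular)
    c = _window_sums(is_c.astype(np.int64), window, step, circular)
    values = np.full(len(g), np.nan)
    ok = (g + c) > 0
    values[ok] = (g[ok] - c[ok]) / (g[ok] + c[ok])
    centers = np.arange(0, len(values)) * step + 1 + window // 2
    tot_g, tot_c = is_g.sum(), is_c.sum()
    mean = float((tot_g - tot_c) / (tot_g + tot_c)) if tot_g + tot_c else float("nan")
    return WindowProfile(replicon.id, window, step, centers, values, "gc_skew", mean)


def cumulative_gc_skew(replicon: Replicon, start_offset: int = 0) -> CumulativeSkewProfile:
    """Running sum of per-base skew (+1 G, -1 C, 0 otherwise), optionally from
    a rotated start; value at position 0 is 0 and the final value is #G - #C."""
    seq = replicon.sequence
    if start_offset:
        seq = seq[start_offset:] + seq[:start_offset]
    is_g, is_c, _ = _base_arrays(seq)
    contrib = is_g.astype(np.int64) - is_c.astype(np.int64)
    values = np.concatenate([[0], np.cumsum(contrib)])
    return CumulativeSkewProfile(replicon.id, np.arange(len(values)), values)


def predict_ori_ter(profile: CumulativeSkewProfile, topology: str = "circular",
                    swap_convention: bool = False) -> OriTerPrediction:
    """ori at the cumulative-skew minimum, ter at the maximum (leading strand
    G-rich).  ``swap_convention`` flips the two calls.  Positions are 1-based;
    an extremum at the 0/L boundary of a circular molecule is reported as L.
    """
    values = profile.values.astype(float)
    L = len(values) - 1
    if L < 1 or np.all(profile.values == 0):
        raise ValueError("no skew signal (flat cumulative profile)")
    note = ""
    if topology == "circular":
        # detrend so extrema are exactly rotation-equivariant
        values = values - np.arange(L + 1) * (values[L] / L)
        cand = values[:L]  # boundary L is identical to 0 after detrending
    else:
        cand = values
        note = "linear molecule: extrema are rotation-dependent; interpret with care"
    i_min = int(np.argmin(cand))
    i_max = int(np.argmax(cand))
    for name, i, extremum in (("minimum", i_min, cand.min()), ("maximum", i_max, cand.max())):
        if (cand == extremum).sum() > 1:
            logger.warning("multiple cumulative-skew %s positions; using smallest", name)
    ori = i_min if i_min >= 1 else L
    ter = i_max if i_max >= 1 else L
    if swap_convention:
        ori, ter = ter, ori
    if ori == ter:
        raise ValueError("degenerate profile: ori and ter coincide")
    return OriTerPrediction(profile.replicon_id, ori, ter,
                            method="cumulative_gc_skew" + ("_detrended" if topology == "circular" else ""),
                            confidence_note=note)


def in_silico_ligation(replicon: Replicon, start: int, end: int) -> Replicon:
    """Excise [start, end] (wrapping allowed on circular molecules) and
    re-circularize it.  Features fully inside are re-coordinated; features
    straddling a cut are dropped with a warning."""
    n = replicon.length
    from .genome_io import extract_region

    seq = extract_region(replicon, start, end)
    if len(seq) == n:
        logger.warning("segment covers the whole replicon; returning a rotation")

    def rel(pos: int) -> Optional[int]:
        if start <= end:
            return pos - start + 1 if start <= pos <= end else None
        if pos >= start:
            return pos - start + 1
        if pos <= end:
            return n - start + 1 + pos
        return None

    kept, dropped = [], 0
    for f in replicon.features:
        if f.wraps_origin:
            dropped += 1
            continue
        s, e = rel(f.start), rel(f.end)
        if s is not None and e is not None and s <= e:
            kept.append(dc_replace(f, start=s, end=e))
        else:
            dropped += 1
    if dropped:
        logger.warning("in_silico_ligation: dropped %d feature(s) straddling a cut", dropped)
    return Replicon(f"{replicon.id}_ligated_{start}_{end}", seq, "circular", kept)
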