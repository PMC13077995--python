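"""Read start/end hotspot statistics in 5-bp genome windows.

For each non-overlapping window the number of reads whose biological 5'
(start) or 3' (end) falls in the window is compared to the mean per-base
coverage there; the ratio is normalised by the genome-wide median ratio to
give a fold change.  Windows with fold >= threshold are hotspot calls.
Start/stop codons near hotspots are annotated, and flanks 5' of start
hotspots are tested for AG (purine) richness against the genome-wide
purine fraction with an exact one-sided binomial test and BH-FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .core_io import AlignedRead, GenomeModel

START_RANGE = (100, 3500)   # 1-based; Fig-style read-start reporting range
END_RANGE = (0, 3400)

_CODON_STOPS = ("TAA", "TAG", "TGA")


def window_site_stats(reads: list[AlignedRead], genome: GenomeModel,
                      window: int = 5, min_depth: float = 50) -> pd.DataFrame:
    """Per-window, per-strand depth and start/end counts with fold changes.

    Start of a read is the biological 5' (genome-min coordinate for '+'
    reads, genome-max for '-'), end is the biological 3'.  ``start_ratio``
    and ``end_ratio`` (count / mean window depth) are computed only where
    depth >= ``min_depth``; elsewhere the window is flagged missing.  Fold
    changes are ratios divided by the genome-wide median ratio over
    qualifying windows of the same strand.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = genome.length
    n_win = (L + window - 1) // window
    frames = []
    for strand in "+-":
        sreads = [r for r in reads if r.strand == strand]
        depth = np.zeros(L + 1)
        starts = np.zeros(n_win, dtype=int)
        ends = np.zeros(n_win, dtype=int)
        for r in sreads:
            depth[r.ref_start] += 1
            depth[r.ref_end] -= 1
            starts[r.bio_start // window] += 1
            ends[r.bio_end // window] += 1
        depth = np.cumsum(depth)[:L]
        pad = np.pad(depth, (0, n_win * window - L), constant_values=np.nan)
        win_depth = np.nanmean(pad.reshape(n_win, window), axis=1)
        ok = win_depth >= min_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            s_ratio = np.where(ok, starts / win_depth, np.nan)
            e_ratio = np.where(ok, ends / win_depth, np.nan)
        s_med = np.nanmedian(s_ratio) if ok.any() else np.nan
        e_med = np.nanmedian(e_ratio) if ok.any() else np.nan
        s_fold = s_ratio / s_med if s_med and s_med > 0 else np.full(n_win, np.nan)
        e_fold = e_ratio / e_med if e_med and e_med > 0 else np.full(n_win, np.nan)
        frames.append(pd.DataFrame({
            "window_start": np.arange(n_win) * window,
            "strand": strand,
            "depth": win_depth,
            "start_count": starts,
            "end_count": ends,
            "start_ratio": s_ratio,
            "end_ratio": e_ratio,
            "start_fold": s_fold,
            "end_fold": e_fold,
            "low_depth": ~ok,
        }))
    return pd.concat(frames, ignore_index=True)


def call_hotspots(window_stats: pd.DataFrame, fold_threshold: float = 5.0,
                  window: int = 5,
                  start_range: tuple[int, int] = START_RANGE,
                  end_range: tuple[int, int] = END_RANGE) -> pd.DataFrame:
    """Call start/end hotspots: fold >= threshold at qualifying depth.

    Position ranges are 1-based inclusive reporting ranges (a window must
    lie wholly inside the range to be called).  Output sorted by fold
    descending, with 1-based window coordinates.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    rows = []
    for _, w in window_stats[~window_stats["low_depth"]].iterrows():
        w1 = int(w["window_start"]) + 1          # 1-based first position
        w2 = int(w["window_start"]) + window     # 1-based last position
        for kind, rng in (("start", start_range), ("end", end_range)):
            fold = w[f"{kind}_fold"]
            if np.isnan(fold) or fold < fold_threshold:
                continue
            if not (w1 >= max(rng[0], 1) and w2 <= rng[1]):
                continue
            rows.append({"kind": kind, "strand": w["strand"],
                         "window_start": w1, "window_end": w2,
                         "count": int(w[f"{kind}_count"]), "depth": w["depth"],
                         "ratio": w[f"{kind}_ratio"], "fold": fold})
    cols = ["kind", "strand", "window_start", "window_end", "count",
            "depth", "ratio", "fold"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("fold", ascending=False, kind="mergesort").reset_index(drop=True)


def annotate_codons(genome: GenomeModel, hotspots: pd.DataFrame,
                    flank: int = 10) -> pd.DataFrame:
    """Annotate each hotspot with ATG/stop-codon occurrences within ±flank nt.

    Codons are searched on both strands by motif (purely annotational).
    Positions reported 1-based.
    """
    seq = genome.sequence
    from .core_io import revcomp

    def _scan(lo: int, hi: int):
        starts, stops = [], []
        for i in range(max(0, lo), min(len(seq) - 2, hi)):
            cod = seq[i:i + 3]
            if cod == "ATG":
                starts.append(i + 1)
            elif cod in _CODON_STOPS:
                stops.append(i + 1)
            rc = revcomp(cod)
            if rc == "ATG":
                starts.append(-(i + 1))  # negative marks '-' strand hit
            elif rc in _CODON_STOPS:
                stops.append(-(i + 1))
        return starts, stops

    out = hotspots.copy()
    col_sc, col_st, col_flag = [], [], []
    for _, h in out.iterrows():
        lo = int(h["window_start"]) - 1 - flank
        hi = int(h["window_end"]) + flank - 2  # last codon start inside flank
        starts, stops = _scan(lo, hi + 1)
        col_sc.append(",".join(map(str, starts)))
        col_st.append(",".join(map(str, stops)))
        col_flag.append(bool(starts))
    out["start_codons"] = col_sc
    out["stop_codons"] = col_st
    out["start_codon_nearby"] = col_flag
    return out


def ag_richness_test(genome: GenomeModel, hotspot_windows: pd.DataFrame,
                     flank: int = 20, strand: str = "-") -> pd.DataFrame:
    """Test the flank 5' of each hotspot for purine (A+G) enrichment.

    The flank is taken strand-aware: for a '+' hotspot the ``flank`` nt
    upstream in genome coordinates; for a '-' hotspot the flank lies at
    higher genome coordinates and purines are counted on the reverse
    complement.  One-sided exact binomial test against the genome-wide
    purine fraction on the same strand; BH-FDR across tested hotspots.
    Flanks truncated at genome ends are noted.
    """
    if flank < 5:
        raise ValueError("flank must be >= 5")
    seq = genome.sequence
    L = genome.length
    if strand == "+":
        background = (seq.count("A") + seq.count("G")) / L
        purines = ("A", "G")
    else:
        background = (seq.count("C") + seq.count("T")) / L
        purines = ("C", "T")  # purines on '-' == C/T on '+'

    rows = []
    for _, h in hotspot_windows.iterrows():
        w1 = int(h["window_start"]) - 1  # 0-based window start
        w2 = int(h["window_end"])        # 0-based exclusive end
        if strand == "+":
            lo, hi = max(0, w1 - flank), w1
        else:
            lo, hi = w2, min(L, w2 + flank)
        flank_seq = seq[lo:hi]
        truncated = len(flank_seq) < flank
        n = len(flank_seq)
        k = sum(flank_seq.count(b) for b in purines)
        frac = k / n if n else np.nan
        if n and background < 1.0:
            p = binomtest(k, n, background, alternative="greater").pvalue
        else:
            p = 1.0
        rows.append({"window_start": h["window_start"], "window_end": h["window_end"],
                     "strand": strand, "purine_fraction": frac, "n_flank": n,
                     "background": background, "p_value": p, "truncated": truncated})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
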