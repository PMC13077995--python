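"""Per-site RNA modification stoichiometry, IVT background subtraction,
significance testing, and temporal dynamics labels.

Nanopore DRS modified-base calling has a high false-positive rate; an
unmodified in vitro transcribed (IVT) control sequenced alongside the test
samples captures the systematic background.  A site is retained only when
stoichiometry(test) - stoichiometry(IVT) > 0 (strict).  Per-site
significance uses a two-sided Fisher exact test on the modified/unmodified
counts of the two samples; Benjamini-Hochberg FDR is applied within each
comparison family (timepoint pair x modification type x read-length
fraction), mirroring per-panel testing.  Temporal dynamics over ordered
timepoints are labelled increase / decrease / no_difference per
consecutive pair at q < alpha.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

DEFAULT_PROB_THRESHOLD = 0.8   # per-read call probability must exceed this (strict)
DEFAULT_MIN_COV = 30
SITE_KEYS = ["ref_pos", "mod_type", "length_fraction"]

#: named dynamic patterns (full-length >3000 nt panels use three timepoints,
#: short <800 nt panels a single 20min-vs-40min comparison)
PRESET_PATTERNS = {
    ("gt3000", ("decrease", "increase")): "blue",
    ("gt3000", ("decrease", "no_difference")): "purple",
    ("gt3000", ("increase", "no_difference")): "brown",
    ("lt800", ("increase",)): "cyan",
    ("lt800", ("no_difference",)): "red",
}


def site_stoichiometry(mod_calls: pd.DataFrame,
                       prob_threshold: float = DEFAULT_PROB_THRESHOLD,
                       min_cov: int = DEFAULT_MIN_COV) -> pd.DataFrame:
    """Aggregate per-read calls into per-site, per-sample stoichiometry.

    ``mod_calls`` needs columns ref_pos, mod_type, probability, sample,
    timepoint and (optionally) length_fraction.  A read is counted modified
    iff its call probability is strictly greater than ``prob_threshold``.
    Sites with coverage below ``min_cov`` are flagged ``low_coverage`` and
    excluded from downstream tests.
    """
    df = mod_calls.copy()
    if "length_fraction" not in df.columns:
        df["length_fraction"] = "all"
    df["modified"] = df["probability"] > prob_threshold
    grouped = (df.groupby(SITE_KEYS + ["sample", "timepoint"], sort=True)
               .agg(coverage=("probability", "size"), n_modified=("modified", "sum"))
               .reset_index())
    grouped["stoichiometry"] = grouped["n_modified"] / grouped["coverage"]
    grouped["low_coverage"] = grouped["coverage"] < min_cov
    return grouped


def ivt_subtract(test_sites: pd.DataFrame, ivt_sites: pd.DataFrame) -> pd.DataFrame:
    """Subtract the IVT background stoichiometry and keep only delta > 0.

    Sites are matched on (ref_pos, mod_type, length_fraction); a test site
    absent from the IVT table gets ivt_stoichiometry = 0.  Rows with
    delta <= 0 are dropped (strict rule).
    """
    ivt = (ivt_sites.groupby(SITE_KEYS)
           .agg(ivt_stoichiometry=("stoichiometry", "mean"),
                ivt_coverage=("coverage", "sum"),
                ivt_n_modified=("n_modified", "sum"))
           .reset_index())
    merged = test_sites.merge(ivt, on=SITE_KEYS, how="left")
    merged["ivt_stoichiometry"] = merged["ivt_stoichiometry"].fillna(0.0)
    merged["ivt_coverage"] = merged["ivt_coverage"].fillna(0).astype(int)
    merged["ivt_n_modified"] = merged["ivt_n_modified"].fillna(0).astype(int)
    merged["delta"] = merged["stoichiometry"] - merged["ivt_stoichiometry"]
    return merged[merged["delta"] > 0].reset_index(drop=True)


def fisher_site_test(n_mod_a: int, cov_a: int, n_mod_b: int, cov_b: int) -> float:
    """Two-sided Fisher exact p for a modified/unmodified x sample 2x2 table."""
    table = [[n_mod_a, cov_a - n_mod_a], [n_mod_b, cov_b - n_mod_b]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def site_significance(sites: pd.DataFrame, family_keys: list[str] | None = None,
                      a_cols: tuple[str, str] = ("n_modified", "coverage"),
                      b_cols: tuple[str, str] = ("ivt_n_modified", "ivt_coverage"),
                      alpha: float = 0.05) -> pd.DataFrame:
    """Fisher exact test per site with BH correction within families.

    By default compares test counts against IVT counts; sites with zero
    coverage in either sample are skipped (dropped with a note column).
    """
    df = sites.copy()
    ok = (df[a_cols[1]] > 0) & (df[b_cols[1]] > 0)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        df["p_value"] = pd.Series(dtype=float)
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["p_value"] = [
        fisher_site_test(int(r[a_cols[0]]), int(r[a_cols[1]]),
                         int(r[b_cols[0]]), int(r[b_cols[1]]))
        for _, r in df.iterrows()]
    if family_keys:
        q = pd.Series(index=df.index, dtype=float)
        for _, idx in df.groupby(family_keys).groups.items():
            q.loc[idx] = multipletests(df.loc[idx, "p_value"], method="fdr_bh")[1]
        df["q_value"] = q
    else:
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["q_value"] < alpha
    return df


def temporal_classification(sites: pd.DataFrame, timepoint_order: list[str],
                            alpha: float = 0.05) -> pd.DataFrame:
    """Label each site's dynamics across ordered timepoints.

    For every consecutive timepoint pair the modified/unmodified counts are
    compared with Fisher's exact test, BH-corrected within the family
    (pair x mod_type x length_fraction); the pair is labelled increase or
    decrease when q < alpha (by the sign of the stoichiometry change), else
    no_difference.  The site's ``dynamic_label`` is the ordered tuple; the
    named convenience patterns (blue/purple/brown/cyan/red) are attached
    where they match.  Sites observed at a single timepoint get
    ``static_insufficient``.
    """
    pair_rows = []
    pairs = list(zip(timepoint_order[:-1], timepoint_order[1:]))
    pivot = sites.set_index(SITE_KEYS + ["timepoint"]).sort_index()
    site_index = sites[SITE_KEYS].drop_duplicates().reset_index(drop=True)
    for _, site in site_index.iterrows():
        key = tuple(site[k] for k in SITE_KEYS)
        for t0, t1 in pairs:
            try:
                r0, r1 = pivot.loc[key + (t0,)], pivot.loc[key + (t1,)]
            except KeyError:
                continue
            if bool(r0.get("low_coverage", False)) or bool(r1.get("low_coverage", False)):
                continue
            p = fisher_site_test(int(r0["n_modified"]), int(r0["coverage"]),
                                 int(r1["n_modified"]), int(r1["coverage"]))
            change = float(r1["stoichiometry"]) - float(r0["stoichiometry"])
            pair_rows.append(dict(zip(SITE_KEYS, key),
                                  pair=f"{t0}_vs_{t1}", p_value=p, change=change))
    pair_df = pd.DataFrame(pair_rows)
    if len(pair_df):
        q = pd.Series(index=pair_df.index, dtype=float)
        for _, idx in pair_df.groupby(["pair", "mod_type", "length_fraction"]).groups.items():
            q.loc[idx] = multipletests(pair_df.loc[idx, "p_value"], method="fdr_bh")[1]
        pair_df["q_value"] = q
        pair_df["label"] = "no_difference"
        sig = pair_df["q_value"] < alpha
        pair_df.loc[sig & (pair_df["change"] > 0), "label"] = "increase"
        pair_df.loc[sig & (pair_df["change"] < 0), "label"] = "decrease"

    out_rows = []
    for _, site in site_index.iterrows():
        key = tuple(site[k] for k in SITE_KEYS)
        if len(pair_df):
            mask = pd.Series(True, index=pair_df.index)
            for k, v in zip(SITE_KEYS, key):
                mask &= pair_df[k] == v
            labels = [pair_df.loc[mask & (pair_df["pair"] == f"{t0}_vs_{t1}"), "label"]
                      for t0, t1 in pairs]
            labels = tuple(l.iloc[0] for l in labels if len(l))
        else:
            labels = ()
        if not labels:
            dyn, preset = "static_insufficient", ""
        else:
            dyn = ",".join(labels)
            preset = PRESET_PATTERNS.get((site["length_fraction"], labels), "")
        out_rows.append(dict(zip(SITE_KEYS, key),
                             dynamic_label=dyn, preset=preset))
    return pd.DataFrame(out_rows)


def site_context(genome, sites: pd.DataFrame, flank: int = 2) -> pd.Series:
    """5-mer (by default) sequence context around each site (annotation only)."""
    seq = genome.sequence
    return sites["ref_pos"].map(
        lambda p: seq[max(0, int(p) - flank):int(p) + flank + 1])
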