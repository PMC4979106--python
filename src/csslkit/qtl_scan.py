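"""Single-marker QTL analysis for substitution-line populations.

Each marker is tested by one-way ANOVA of line-mean phenotype on genotype
group (recurrent vs donor homozygotes, with heterozygotes as a third group
when enough lines carry one).  Reported per marker:

* ``p_value`` — F-test p-value;
* ``pve_percent`` — phenotypic variance explained, 100 x SS_between/SS_total
  (the R^2 of the one-marker model);
* ``add_effect`` — additive effect, (mean_D - mean_R) / 2, the substitution
  line convention: a negative value means the donor allele decreases the
  trait.

Significant markers are clustered into named QTLs per trait and chromosome
(``q`` + trait code + chromosome + ``-`` + index, e.g. ``qDTH10-1``), with a
two-site consistency flag for multi-environment designs.  No multiple-testing
correction is applied by default (single-point analysis at a fixed threshold,
conventionally P < 0.01); a Bonferroni option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default trait-name -> code mapping used in QTL names.
DEFAULT_TRAIT_CODES = {
    "days_to_heading": "DTH",
    "seed_shattering": "SH",
    "plant_height": "PH",
    "panicles_per_plant": "PPP",
    "grains_per_panicle": "GPP",
    "grain_length": "GL",
    "grain_width": "GW",
    "thousand_grain_weight": "TGW",
    "flag_leaf_length": "LFL",
    "flag_leaf_width": "WFL",
}

_MIN_P = 1e-300


def trait_code(trait: str, codes: dict[str, str] | None = None) -> str:
    codes = {**DEFAULT_TRAIT_CODES, **(codes or {})}
    if trait in codes:
        return codes[trait]
    parts = [p for p in trait.replace("-", "_").split("_") if p]
    return "".join(p[0].upper() for p in parts) or trait.upper()


def line_means(
    phenotypes: pd.DataFrame, trait: str, site: str
) -> pd.Series:
    """Mean phenotype per line across replicates for one trait at one site."""
    sub = phenotypes[(phenotypes["trait"] == trait) & (phenotypes["site"] == site)]
    if sub.empty:
        raise ValidationError(f"no phenotype records for trait {trait!r} at site {site!r}")
    return sub.groupby("line")["value"].mean()


def _anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA p-value and PVE (%) over >= 2 groups."""
    values = np.concatenate(groups)
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total == 0.0:
        return 1.0, 0.0
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    if df_w <= 0:
        return 1.0, 100.0 * ss_between / ss_total
    if ss_within <= 0.0:
        return _MIN_P, 100.0 * ss_between / ss_total
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return max(p, _MIN_P), 100.0 * ss_between / ss_total


def single_point_scan(
    matrix: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    site: str,
    min_group: int = 3,
) -> pd.DataFrame:
    """Marker-by-marker association scan of one trait at one site.

    Lines without phenotype records are ignored; markers where fewer than two
    genotype groups reach ``min_group`` lines are skipped (monomorphic or
    near-monomorphic columns).
    """
    means = line_means(phenotypes, trait, site)
    common = [lid for lid in matrix.line_ids if lid in means.index]
    if not common:
        raise ValidationError("no phenotyped lines present in the genotype matrix")
    y = means.loc[common].to_numpy(dtype=float)
    calls = matrix.calls.loc[common]
    gmap = matrix.map

    rows = []
    tested = 0
    for marker, chrom, cm in zip(gmap.table["marker"], gmap.table["chromosome"], gmap.table["cm"]):
        col = calls[marker].to_numpy()
        group_vals: dict[str, np.ndarray] = {}
        for code in ("R", "D", "H"):
            vals = y[col == code]
            if len(vals):
                group_vals[code] = vals
        ns = {c: len(v) for c, v in group_vals.items()}
        usable = {c: v for c, v in group_vals.items() if len(v) >= min_group}
        if len(usable) < 2:
            continue
        tested += 1
        p, pve = _anova(list(usable.values()))
        add = np.nan
        if "D" in usable and "R" in usable:
            add = (usable["D"].mean() - usable["R"].mean()) / 2.0
        rows.append(
            {
                "trait": trait, "site": site, "marker": marker,
                "chromosome": chrom, "cm": cm,
                "p_value": p, "pve_percent": pve, "add_effect": add,
                "n_R": ns.get("R", 0), "n_D": ns.get("D", 0), "n_H": ns.get("H", 0),
                "mean_R": float(group_vals["R"].mean()) if "R" in group_vals else np.nan,
                "mean_D": float(group_vals["D"].mean()) if "D" in group_vals else np.nan,
                "mean_H": float(group_vals["H"].mean()) if "H" in group_vals else np.nan,
            }
        )
    if tested == 0:
        logger.warning("no testable markers for trait %s at %s", trait, site)
    return pd.DataFrame(
        rows,
        columns=["trait", "site", "marker", "chromosome", "cm", "p_value",
                 "pve_percent", "add_effect", "n_R", "n_D", "n_H",
                 "mean_R", "mean_D", "mean_H"],
    )


def scan_all(
    matrix: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    traits: list[str] | None = None,
    sites: list[str] | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Scan every (trait, site) combination and concatenate the results."""
    traits = traits or sorted(phenotypes["trait"].unique())
    sites = sites or sorted(phenotypes["site"].unique())
    frames = [
        single_point_scan(matrix, phenotypes, t, s, min_group=min_group)
        for t in traits for s in sites
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


@dataclass(frozen=True)
class QTLRecord:
    name: str
    trait: str
    marker: str
    chromosome: str
    cm: float
    per_site: dict
    consistent_all_sites: bool
    direction_agreement: bool


def declare_qtls(
    scans: pd.DataFrame,
    p_threshold: float = 0.01,
    window_cm: float = 20.0,
    trait_codes: dict[str, str] | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Cluster significant markers into named QTLs.

    Markers significant at any site are grouped per trait and chromosome;
    consecutive significant markers within ``window_cm`` collapse into one QTL
    located at the most significant marker.  A QTL is ``consistent_all_sites``
    when every site in ``scans`` shows significance somewhere in its cluster.
    With ``bonferroni`` the threshold is divided by the number of tested
    markers per (trait, site).
    """
    if scans.empty:
        return pd.DataFrame(
            columns=["qtl", "trait", "marker", "chromosome", "cm",
                     "site", "p_value", "pve_percent", "add_effect",
                     "consistent_all_sites", "direction_agreement"])
    sites = sorted(scans["site"].unique())
    rows = []
    for trait, tf in scans.groupby("trait", sort=True):
        thr = p_threshold
        if bonferroni:
            thr = p_threshold / tf.groupby("site")["marker"].nunique().max()
        sig = tf[tf["p_value"] < thr]
        if sig.empty:
            continue
        code = trait_code(trait, trait_codes)
        for chrom in sorted(sig["chromosome"].unique(), key=str):
            cf = sig[sig["chromosome"] == chrom]
            marker_pos = (
                cf.groupby("marker")
                .agg(cm=("cm", "first"), min_p=("p_value", "min"))
                .sort_values("cm")
            )
            clusters: list[list[str]] = []
            prev_cm = None
            for marker, r in marker_pos.iterrows():
                if prev_cm is None or r["cm"] - prev_cm > window_cm:
                    clusters.append([marker])
                else:
                    clusters[-1].append(marker)
                prev_cm = r["cm"]
            for idx, members in enumerate(clusters, start=1):
                rep = marker_pos.loc[members, "min_p"].idxmin()
                name = f"q{code}{chrom}-{idx}"
                cluster_rows = tf[tf["marker"].isin(members)]
                consistent = all(
                    (cluster_rows[(cluster_rows["site"] == s)]["p_value"] < thr).any()
                    for s in sites
                )
                rep_rows = tf[tf["marker"] == rep]
                adds = rep_rows["add_effect"].dropna()
                direction = bool(len(adds) and (np.sign(adds) == np.sign(adds.iloc[0])).all())
                for s in sites:
                    rr = rep_rows[rep_rows["site"] == s]
                    rows.append(
                        {
                            "qtl": name, "trait": trait, "marker": rep,
                            "chromosome": chrom, "cm": float(marker_pos.loc[rep, "cm"]),
                            "site": s,
                            "p_value": float(rr["p_value"].iloc[0]) if len(rr) else np.nan,
                            "pve_percent": float(rr["pve_percent"].iloc[0]) if len(rr) else np.nan,
                            "add_effect": float(rr["add_effect"].iloc[0]) if len(rr) else np.nan,
                            "consistent_all_sites": consistent,
                            "direction_agreement": direction,
                        }
                    )
    return pd.DataFrame(rows)


def compare_to_recurrent(
    phenotypes: pd.DataFrame,
    line: str,
    trait: str,
    site: str,
    recurrent: str = "9311",
    equal_var: bool = False,
) -> tuple[float, float]:
    """Welch two-sample t-test of a line's replicate values against the
    recurrent parent's; returns ``(t, p)``."""
    sub = phenotypes[(phenotypes["trait"] == trait) & (phenotypes["site"] == site)]
    a = sub[sub["line"] == line]["value"].to_numpy(dtype=float)
    b = sub[sub["line"] == recurrent]["value"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"need >=2 replicates for both {line!r} ({len(a)}) and {recurrent!r} ({len(b)})"
        )
    if np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def trait_correlations(
    phenotypes: pd.DataFrame, site: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of line means between traits at one site.

    Returns ``(r, p, flags)`` square frames; flags are ``"**"`` (p < 0.01),
    ``"*"`` (p < 0.05) or empty.  Pairs are computed on pairwise-complete
    lines; at least three complete pairs are required per entry.
    """
    sub = phenotypes[phenotypes["site"] == site]
    wide = sub.groupby(["line", "trait"])["value"].mean().unstack()
    traits = list(wide.columns)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < 3:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    flags = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    np.fill_diagonal(flags.values, "")
    return r, p, flags
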