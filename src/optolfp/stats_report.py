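"""Statistical battery over per-animal summaries, and pipeline assembly.

Statistics always run on per-animal values after averaging technical
replicates (n = animals, never pooled sessions).  Hour-wise baseline-
subtracted values are tested with one-sample t tests under a Bonferroni-
corrected level (alpha = 0.05/2 for the two post-baseline hours); matched
designs use paired t / repeated-measures ANOVA with Tukey's post hoc;
non-parametric three-group designs use Friedman (matched) or
Kruskal-Wallis (independent) with Dunn's post hoc; band-by-hour tables use
two-way repeated-measures ANOVA with Dunnett's comparisons against the
baseline hour.  All p-values are two-tailed and reported with their alpha.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sst

from . import linelength, preprocess, spectral, epileptiform
from .io_core import SessionLayout, ValidationError
from .synthetic_lfp import default_config, simulate_experiment

__all__ = [
    "StatResult",
    "ReportBundle",
    "average_replicates",
    "one_sample_t",
    "paired_t",
    "rm_anova",
    "two_way_rm_anova",
    "posthoc",
    "rank_tests",
    "pearson_r",
    "run_pipeline",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    df: object
    p: float
    alpha: float = 0.05
    posthoc: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.p <= 1 or np.isnan(self.p)):
            raise ValidationError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["statistic"] = float(self.statistic)
        return d


def average_replicates(values: pd.DataFrame, group_cols, value_col: str = "value"
                       ) -> pd.DataFrame:
    """Arithmetic mean across technical replicates.

    ``group_cols`` typically is ``["animal", "session_type", ...]``; the
    returned frame has one row per group, so downstream n = animals.
    """
    out = (values.groupby(list(group_cols), as_index=False)[value_col]
           .mean())
    return out


def one_sample_t(values, mu: float = 0.0, n_comparisons: int = 1) -> StatResult:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("one-sample t needs n >= 2")
    if np.std(values, ddof=1) == 0:
        raise ValidationError("zero variance: t statistic undefined")
    t, p = sst.ttest_1samp(values, popmean=mu)
    return StatResult(test="one-sample t", statistic=float(t),
                      df=values.size - 1, p=float(p),
                      alpha=0.05 / n_comparisons,
                      extra={"mu": mu, "mean": float(values.mean()),
                             "sem": float(sst.sem(values)), "n": values.size})


def paired_t(a, b, n_comparisons: int = 1) -> StatResult:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired t needs equal-length samples")
    res = one_sample_t(a - b, 0.0, n_comparisons)
    res.test = "paired t"
    return res


def rm_anova(data: np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA on a complete subject x condition
    table (no sphericity correction).  With two conditions, F equals the
    square of the paired t statistic."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("rm_anova expects a subject x condition table")
    if np.isnan(data).any():
        raise ValidationError("missing cells: no imputation is done")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError("rm_anova needs >= 2 subjects and conditions")
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df2
    if ms_err == 0:
        F = 0.0 if ss_cond == 0 else np.inf
    else:
        F = (ss_cond / df1) / ms_err
    p = float(sst.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return StatResult(test="RM ANOVA", statistic=float(F), df=(df1, df2), p=p,
                      extra={"n_subjects": n, "n_conditions": k})


def two_way_rm_anova(df: pd.DataFrame, dv: str, within: list, subject: str
                     ) -> dict:
    """Two-way repeated-measures ANOVA (e.g. band x hour), both factors
    within-subject; returns a StatResult per effect (uncorrected p)."""
    import pingouin as pg
    table = pg.rm_anova(data=df, dv=dv, within=list(within), subject=subject,
                        detailed=True)
    out = {}
    for _, row in table.iterrows():
        if row["Source"] in ("Within", "Error"):
            continue
        out[row["Source"]] = StatResult(
            test=f"two-way RM ANOVA [{row['Source']}]",
            statistic=float(row["F"]), df=(row["ddof1"], row["ddof2"]),
            p=float(row["p_unc"]))
    return out


def _dunn(groups, alpha: float = 0.05) -> list:
    """Dunn's rank-based post hoc with Bonferroni scaling over the tested
    pairs (two-tailed)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sst.rankdata(pooled)
    N = pooled.size
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N) if N > 1 else 1.0
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start:start + s].mean())
        start += s
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(tie * N * (N + 1) / 12.0
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_unadj = 2 * sst.norm.sf(abs(z))
            rows.append({"pair": (i, j), "statistic": float(z),
                         "p_unadjusted": float(p_unadj),
                         "p_adjusted": float(min(1.0, p_unadj * m))})
    return rows


def posthoc(groups, method: str, control: int = 0) -> list:
    """Pairwise multiple comparisons after an omnibus test.

    ``method``: 'tukey' (all pairs), 'dunnett' (each treatment vs the
    ``control`` group index), or 'dunn' (rank-based, Bonferroni-scaled).
    Returns a list of dicts with the pair and adjusted p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if method == "tukey":
        res = sst.tukey_hsd(*groups)
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append({"pair": (i, j),
                             "statistic": float(res.statistic[i, j]),
                             "p_adjusted": float(min(1.0, res.pvalue[i, j]))})
        return rows
    if method == "dunnett":
        treats = [g for i, g in enumerate(groups) if i != control]
        idx = [i for i in range(len(groups)) if i != control]
        res = sst.dunnett(*treats, control=groups[control])
        return [{"pair": (control, i), "statistic": float(s),
                 "p_adjusted": float(p)}
                for i, s, p in zip(idx, np.atleast_1d(res.statistic),
                                   np.atleast_1d(res.pvalue))]
    if method == "dunn":
        return _dunn(groups)
    raise ValidationError(f"unknown post-hoc method {method!r}")


def rank_tests(groups, design: str) -> StatResult:
    """Friedman chi-square (matched; groups are condition columns of a
    complete table) or Kruskal-Wallis H with tie correction (independent).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if design == "friedman":
        if len(groups) < 3:
            raise ValidationError("Friedman needs >= 3 conditions")
        stat, p = sst.friedmanchisquare(*groups)
        return StatResult(test="Friedman", statistic=float(stat),
                          df=len(groups) - 1, p=float(p))
    if design == "kruskal":
        if len(groups) < 2:
            raise ValidationError("Kruskal-Wallis needs >= 2 groups")
        stat, p = sst.kruskal(*groups)
        return StatResult(test="Kruskal-Wallis", statistic=float(stat),
                          df=len(groups) - 1, p=float(p))
    raise ValidationError(f"unknown rank design {design!r}")


def pearson_r(x, y) -> StatResult:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValidationError("Pearson r needs matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = sst.pearsonr(x, y)
    return StatResult(test="Pearson r", statistic=float(r), df=x.size - 2,
                      p=float(p))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "master_seed": 0,
    "fs_raw": 1000.0,
    "fs_analysis": 500.0,
    "hour_s": 600.0,
    "fadeoff_s": 100.0,
    "group": "PACK",
    "treatment": "saline",
    "n_animals": 6,
    "session_types": ["ref", "stim_0.1"],
    "n_replicates": 2,
}


@dataclass
class ReportBundle:
    """Tidy tables plus a stats appendix and provenance record."""

    hourly: pd.DataFrame
    pulse_response: pd.DataFrame
    band_power: pd.DataFrame
    burst_ratio: pd.DataFrame
    gs_counts: pd.DataFrame
    stats: dict
    provenance: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in [("hourly_line_length", self.hourly),
                         ("pulse_response", self.pulse_response),
                         ("band_power", self.band_power),
                         ("burst_ratio", self.burst_ratio),
                         ("gs_counts", self.gs_counts)]:
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        (out / "stats.json").write_text(
            json.dumps(self.stats, indent=2, sort_keys=True, default=str) + "\n")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")
        return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]


def analyze_session(rec, layout: SessionLayout, fs_analysis: float = 500.0):
    """Per-session feature extraction shared by pipeline and scripts.

    Returns a dict with hourly line length, pulse response (stim sessions),
    hourly band power (analysis channel), burst summaries per channel
    (kainate), and the GS count.
    """
    stim = rec.meta.get("session", "ref") != "ref"
    chan = rec.meta.get("analysis_channel", rec.labels[-1])
    sig = preprocess.build_mask(rec, labels=("GS",), channel=chan,
                                fs_out=fs_analysis)
    out = {"hourly": linelength.hourly_line_length(sig, layout, stim=stim)}
    if stim:
        out["pulse"] = linelength.pulse_triggered(
            sig, rec.pulse_onsets(), layout)
    raw = preprocess.build_mask(rec, labels=("GS",), channel=chan)
    out["bands"] = spectral.hourly_band_power(raw, layout, stim=stim)
    if rec.meta.get("treatment") == "kainate":
        out["bursts"] = {}
        for label in rec.labels:
            s = preprocess.build_mask(rec, labels=("GS",), channel=label,
                                      fs_out=fs_analysis)
            spikes = epileptiform.detect_spikes(s, channel=label)
            bursts = epileptiform.group_bursts(spikes)
            out["bursts"][label] = epileptiform.burst_ratio(
                bursts, s.duration, rec.annotations, channel=label)
    out["gs_count"] = len(rec.annotations.intervals("GS"))
    return out


def run_pipeline(config: dict | None = None) -> ReportBundle:
    """Simulate a cohort, run every analysis stage, and assemble the report.

    Fully deterministic under a fixed ``master_seed`` (per-session seeds are
    spawned from it); the bundle contains no wall-clock state, so repeated
    runs are byte-identical.
    """
    cfg = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    layout = SessionLayout(hour_s=cfg["hour_s"], fadeoff_s=cfg["fadeoff_s"])
    ss = np.random.SeedSequence(cfg["master_seed"])
    hourly_rows, pulse_rows, band_rows, burst_rows, gs_rows = [], [], [], [], []

    session_seeds = {}
    for animal in range(cfg["n_animals"]):
        for st in cfg["session_types"]:
            for rep in range(cfg["n_replicates"]):
                seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                session_seeds[f"a{animal}_{st}_r{rep}"] = seed
                sim = default_config(
                    group=cfg["group"], treatment=cfg["treatment"],
                    session=st, layout=layout, fs_raw=cfg["fs_raw"],
                    seed=seed)
                rec, _ = simulate_experiment(sim)
                res = analyze_session(rec, layout, cfg["fs_analysis"])
                base = {"animal": animal, "session_type": st, "replicate": rep}
                for h, d in res["hourly"].deltas.items():
                    hourly_rows.append({**base, "hour": h, "metric": "delta_L",
                                        "value": d})
                    hourly_rows.append({**base, "hour": h, "metric": "L",
                                        "value": res["hourly"].hours[h]})
                if "pulse" in res:
                    for k, v in res["pulse"].means().items():
                        pulse_rows.append({**base, "metric": k, "value": v})
                for h, bands in res["bands"].deltas.items():
                    for b, v in bands.items():
                        band_rows.append({**base, "hour": h, "band": b,
                                          "metric": "delta_auc", "value": v})
                        band_rows.append({**base, "hour": h, "band": b,
                                          "metric": "auc",
                                          "value": res["bands"].hours[h][b]})
                if "bursts" in res:
                    for label, summ in res["bursts"].items():
                        burst_rows.append({**base, "channel": label,
                                           "dropped_gs": summ.dropped_gs,
                                           "value": summ.ratio})
                gs_rows.append({**base, "value": res["gs_count"]})

    hourly = pd.DataFrame(hourly_rows)
    pulse = pd.DataFrame(pulse_rows)
    bands = pd.DataFrame(band_rows)
    bursts = pd.DataFrame(burst_rows)
    gs = pd.DataFrame(gs_rows)

    stats = {}
    deltas = hourly[hourly["metric"] == "delta_L"]
    for st in cfg["session_types"]:
        per_animal = average_replicates(
            deltas[deltas["session_type"] == st],
            ["animal", "hour"])
        for h in sorted(per_animal["hour"].unique()):
            if h == 1:
                continue
            vals = per_animal[per_animal["hour"] == h]["value"].to_numpy()
            try:
                stats[f"delta_L_{st}_hour{h}"] = one_sample_t(
                    vals, 0.0, n_comparisons=2).to_dict()
            except ValidationError as exc:
                stats[f"delta_L_{st}_hour{h}"] = {"error": str(exc)}
    if len(pulse):
        for st in pulse["session_type"].unique():
            pa = average_replicates(pulse[pulse["session_type"] == st],
                                    ["animal", "metric"])
            wide = pa.pivot(index="animal", columns="metric", values="value")
            table = wide[["pre", "before", "after"]].to_numpy()
            res = rm_anova(table)
            res.posthoc = posthoc([table[:, i] for i in range(3)], "tukey")
            res.extra["conditions"] = ["pre", "before", "after"]
            stats[f"pulse_response_{st}"] = res.to_dict()
    gs_per_animal = average_replicates(gs, ["animal", "session_type"])
    stats["gs_total"] = {
        "mean_per_session": float(gs_per_animal["value"].mean()),
        "n_animals": cfg["n_animals"],
    }

    provenance = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "session_seeds": session_seeds,
    }
    return ReportBundle(hourly=hourly, pulse_response=pulse, band_power=bands,
                        burst_ratio=bursts, gs_counts=gs, stats=stats,
                        provenance=provenance)
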