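"""End-to-end orchestration: synthetic data -> features -> ages -> rates ->
potential -> stability -> robustness -> statistics -> report bundle.

Each stage can be disabled; a stage whose prerequisites failed or were
disabled is skipped with an explicit status. All randomness derives from
the single pipeline seed, so a fixed configuration reproduces the bundle
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import homology as hm
from . import potential as pt
from . import rates as rt
from . import robustness as rb
from . import stats as st
from . import synthetic as syn
from .homology import AgeClass

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("structage.pipeline")

ALL_STAGES = (
    "simulate",
    "features",
    "age",
    "rates",
    "potential",
    "score",
    "robustness",
    "stats",
)

SS_CATEGORIES = ("helix", "sheet", "turn", "coil")
EXPOSURE_CATEGORIES = ("exposed", "buried")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path | None = None
    ages: tuple = (AgeClass.eukarya, AgeClass.metazoa, AgeClass.vertebrata)
    n_structures_per_age: int = 30
    chain_length_range: tuple[int, int] = (80, 220)
    n_codons_per_bin: int = 50_000
    n_training_structures: int = 100
    n_robustness_replicates: int = 1000
    robustness_denominator: int = 50
    length_bin_width: int = 25
    n_bootstrap_se: int = 50
    make_plots: bool = True
    disabled_stages: tuple = ()

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables the report derives, plus stage status and run manifest."""

    structure_table: pd.DataFrame | None = None
    feature_table: pd.DataFrame | None = None
    age_table: pd.DataFrame | None = None
    bin_series_by_age: dict = field(default_factory=dict)
    fig1_table: pd.DataFrame | None = None  # dN per RSA bin per age
    slope_fits: dict = field(default_factory=dict)
    interaction_fits: dict = field(default_factory=dict)
    pearson_by_age: dict = field(default_factory=dict)
    fig2_table: pd.DataFrame | None = None  # fraction exposed comparisons
    figs2_table: pd.DataFrame | None = None  # omega comparisons by age
    fig3_table: pd.DataFrame | None = None  # robustness rank comparisons
    table1: pd.DataFrame | None = None  # category x age-pair p-value matrix
    stability_pairing: pd.DataFrame | None = None
    stability_test: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _features_from_synthetic(structure: syn.SyntheticStructure) -> list[ft.ResidueFeature]:
    """Per-residue features straight from the generator's planted DSSP data."""
    out = []
    for i, res in enumerate(structure.residues):
        rsa = ft.compute_rsa(res.amino_acid, structure.asa[i])
        exposure, rbin, cat = ft.classify_residue(rsa, structure.ss_letters[i])
        out.append(
            ft.ResidueFeature(i + 1, res.amino_acid, structure.asa[i], rsa, exposure, rbin, cat)
        )
    return out


def _pairwise(ages: list) -> list[tuple]:
    return [(ages[i], ages[j]) for i in range(len(ages)) for j in range(i + 1, len(ages))]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis on synthetic data and assemble the report."""
    bundle = ReportBundle()
    enabled = {s: s not in config.disabled_stages for s in ALL_STAGES}
    status = bundle.status
    master = np.random.default_rng(config.seed)
    seeds = {name: int(master.integers(2**31)) for name in ALL_STAGES}
    ages = [AgeClass(a) if not isinstance(a, AgeClass) else a for a in config.ages]
    age_names = [str(a) for a in ages]

    structures: dict[str, syn.SyntheticStructure] = {}
    feats: dict[str, list[ft.ResidueFeature]] = {}
    alignments: dict[str, rt.CodonAlignment] = {}
    profiles: dict[str, list[hm.HitRecord]] = {}
    planted_age: dict[str, AgeClass] = {}
    model: pt.PotentialModel | None = None

    # ---- simulate -------------------------------------------------------
    if enabled["simulate"]:
        try:
            rng = np.random.default_rng(seeds["simulate"])
            for age in ages:
                for k in range(config.n_structures_per_age):
                    length = int(rng.integers(*config.chain_length_range))
                    cfg = syn.config_for_age(
                        age, chain_length=length, seed=int(rng.integers(2**31))
                    )
                    stc = syn.generate_toy_structure(cfg)
                    stc.id = f"{age}_{k:04d}"
                    structures[stc.id] = stc
                    planted_age[stc.id] = age
                    f = _features_from_synthetic(stc)
                    feats[stc.id] = f
                    alignments[stc.id] = syn.generate_ortholog_pair(
                        stc, f, cfg, seed=int(rng.integers(2**31))
                    )
                    profiles[stc.id], _ = syn.generate_homolog_profile(
                        age, seed=int(rng.integers(2**31)), query_id=stc.id
                    )
            status["simulate"] = "ok"
        except Exception as exc:  # pragma: no cover - defensive
            log.exception("simulate stage failed")
            status["simulate"] = f"failed: {exc}"
    else:
        status["simulate"] = "disabled"

    have_data = status["simulate"] == "ok"

    # ---- features -------------------------------------------------------
    if enabled["features"] and have_data:
        bundle.feature_table = pd.concat(
            [
                pd.DataFrame(
                    [
                        (sid, f.position, f.amino_acid, f.asa, f.rsa, f.exposure,
                         f.rsa_bin, f.ss_category)
                        for f in fl
                    ],
                    columns=["structure", "position", "aa", "asa", "rsa",
                             "exposure", "rsa_bin", "ss_category"],
                )
                for sid, fl in feats.items()
            ],
            ignore_index=True,
        )
        status["features"] = "ok"
    else:
        status["features"] = "disabled" if not enabled["features"] else "skipped: no data"

    # ---- age ------------------------------------------------------------
    assigned_age: dict[str, AgeClass] = {}
    if enabled["age"] and have_data:
        rows = []
        for sid, hits in profiles.items():
            age, excluded = hm.assign_age(hits)
            assigned_age[sid] = age
            rows.append((sid, str(age), excluded))
        bundle.age_table = pd.DataFrame(rows, columns=["structure", "age_class", "excluded"])
        status["age"] = "ok"
    else:
        if have_data:
            assigned_age = dict(planted_age)
        status["age"] = "disabled" if not enabled["age"] else "skipped: no data"
    if not assigned_age and have_data:
        assigned_age = dict(planted_age)

    # ---- per-structure table -------------------------------------------
    if have_data:
        rows = []
        for sid, stc in structures.items():
            est = rt.estimate_dn_ds(alignments[sid])
            retained, reason = rt.apply_rate_filters(est, len(stc))
            rows.append(
                {
                    "structure": sid,
                    "age_class": str(assigned_age.get(sid, planted_age[sid])),
                    "length": len(stc),
                    "fraction_exposed": ft.fraction_exposed(feats[sid]),
                    "dn": est.dn,
                    "ds": est.ds,
                    "omega": est.omega if est.omega is not None else np.nan,
                    "rate_retained": retained,
                    "rate_filter_reason": reason,
                }
            )
        bundle.structure_table = pd.DataFrame(rows)

    # ---- rates: per-category and per-bin --------------------------------
    category_rates: pd.DataFrame | None = None
    if enabled["rates"] and have_data:
        try:
            ages_str = {sid: str(a) for sid, a in assigned_age.items()}
            rows = []
            for grouping in ("ss_category", "exposure"):
                for sid in structures:
                    groups = rt.concatenate_by_category(
                        {sid: feats[sid]}, {sid: alignments[sid]}, grouping
                    )
                    for key, aln in groups.items():
                        est = rt.estimate_dn_ds(aln)
                        rows.append(
                            {
                                "structure": sid,
                                "age_class": ages_str[sid],
                                "category": key,
                                "n_codons": aln.n_codons,
                                "dn": est.dn,
                                "ds": est.ds,
                                "omega": est.omega if est.omega is not None else np.nan,
                            }
                        )
            category_rates = pd.DataFrame(rows)

            rng = np.random.default_rng(seeds["rates"])
            for age in ages:
                cfg = syn.config_for_age(age, seed=int(rng.integers(2**31)))
                per_bin = syn.generate_binned_codon_data(cfg, config.n_codons_per_bin)
                series = st.bin_series_from_estimates(
                    per_bin,
                    age=str(age),
                    n_boot=config.n_bootstrap_se,
                    seed=int(rng.integers(2**31)),
                )
                bundle.bin_series_by_age[str(age)] = series
            bundle.fig1_table = pd.concat(
                [s.to_frame() for s in bundle.bin_series_by_age.values()],
                ignore_index=True,
            )
            status["rates"] = "ok"
        except Exception as exc:
            log.exception("rates stage failed")
            status["rates"] = f"failed: {exc}"
    else:
        status["rates"] = "disabled" if not enabled["rates"] else "skipped: no data"

    # ---- potential ------------------------------------------------------
    if enabled["potential"]:
        try:
            rng = np.random.default_rng(seeds["potential"])
            corpus = []
            for k in range(config.n_training_structures):
                age = ages[k % len(ages)]
                length = int(rng.integers(*config.chain_length_range))
                cfg = syn.config_for_age(
                    age, chain_length=length, seed=int(rng.integers(2**31))
                )
                corpus.append(syn.generate_toy_structure(cfg))
            model = pt.train_potential(corpus)
            status["potential"] = "ok"
        except Exception as exc:
            log.exception("potential stage failed")
            status["potential"] = f"failed: {exc}"
    else:
        status["potential"] = "disabled"

    # ---- score ----------------------------------------------------------
    if enabled["score"] and model is not None and have_data:
        try:
            dgs = {
                sid: pt.score_structure(stc, stc.sequence, model).delta_g
                for sid, stc in structures.items()
            }
            bundle.structure_table["delta_g"] = bundle.structure_table["structure"].map(dgs)
            groups = {}
            for sid, stc in structures.items():
                groups.setdefault(str(assigned_age[sid]), []).append((len(stc), dgs[sid]))
            pairing, excluded = st.length_bin_pairing(
                groups, bin_width=config.length_bin_width, seed=seeds["score"]
            )
            bundle.stability_pairing = pairing
            bundle.stability_test = {"excluded_groups": excluded}
            kept = [g for g in groups if g not in excluded]
            for ga, gb in _pairwise(kept):
                va = pairing[pairing.group == ga].value.to_numpy()
                vb = pairing[pairing.group == gb].value.to_numpy()
                if len(va) == len(vb) and len(va) > 0:
                    try:
                        stat, p = st.wilcoxon_test(va, vb, paired=True)
                    except st.DegenerateDataError:
                        stat, p = np.nan, np.nan
                    bundle.stability_test[(ga, gb)] = {
                        "p": p,
                        "median_a": float(np.median(va)),
                        "median_b": float(np.median(vb)),
                        "n_pairs": len(va),
                    }
            status["score"] = "ok"
        except Exception as exc:
            log.exception("score stage failed")
            status["score"] = f"failed: {exc}"
    else:
        status["score"] = (
            "disabled" if not enabled["score"] else "skipped: needs potential + data"
        )

    # ---- robustness -----------------------------------------------------
    if enabled["robustness"] and model is not None and have_data:
        try:
            rng = np.random.default_rng(seeds["robustness"])
            rows = []
            for sid, stc in structures.items():
                pop = rb.build_mutant_population(
                    stc,
                    model,
                    denominator=config.robustness_denominator,
                    n_replicates=config.n_robustness_replicates,
                    seed=int(rng.integers(2**31)),
                )
                rows.append(
                    {
                        "structure": sid,
                        "age_class": str(assigned_age[sid]),
                        "native_dg": pop.native_dg,
                        "mutant_mean": float(np.mean(pop.mutant_dgs)),
                        "mutant_sd": float(np.std(pop.mutant_dgs, ddof=1)),
                        "z_score": pop.z_score,
                        "rank": pop.rank,
                        "denominator": pop.mutation_rate_denominator,
                        "n_replicates": len(pop.mutant_dgs),
                    }
                )
            robust = pd.DataFrame(rows)
            bundle.structure_table = bundle.structure_table.merge(
                robust[["structure", "z_score", "rank"]], on="structure", how="left"
            )
            comp_rows = []
            for ga, gb in _pairwise(age_names):
                for metric in ("z_score", "rank"):
                    va = robust.loc[robust.age_class == ga, metric].to_numpy()
                    vb = robust.loc[robust.age_class == gb, metric].to_numpy()
                    if len(va) and len(vb):
                        _, p = st.wilcoxon_test(va, vb)
                        comp_rows.append(
                            (metric, ga, gb, float(np.median(va)), float(np.median(vb)), p)
                        )
            bundle.fig3_table = pd.DataFrame(
                comp_rows, columns=["metric", "age_a", "age_b", "median_a", "median_b", "p"]
            )
            status["robustness"] = "ok"
        except Exception as exc:
            log.exception("robustness stage failed")
            status["robustness"] = f"failed: {exc}"
    else:
        status["robustness"] = (
            "disabled" if not enabled["robustness"] else "skipped: needs potential + data"
        )

    # ---- stats ----------------------------------------------------------
    if enabled["stats"] and have_data:
        try:
            stbl = bundle.structure_table
            # fraction-exposed comparisons across ages (designability analogue)
            rows = []
            for ga, gb in _pairwise(age_names):
                va = stbl.loc[stbl.age_class == ga, "fraction_exposed"].to_numpy()
                vb = stbl.loc[stbl.age_class == gb, "fraction_exposed"].to_numpy()
                _, p = st.wilcoxon_test(va, vb)
                rows.append((ga, gb, float(np.median(va)), float(np.median(vb)), p))
            bundle.fig2_table = pd.DataFrame(
                rows, columns=["age_a", "age_b", "median_a", "median_b", "p"]
            )
            # omega (dN/dS) comparisons across ages
            rows = []
            for ga, gb in _pairwise(age_names):
                va = stbl.loc[stbl.age_class == ga, "omega"].dropna().to_numpy()
                vb = stbl.loc[stbl.age_class == gb, "omega"].dropna().to_numpy()
                if len(va) and len(vb):
                    _, p = st.wilcoxon_test(va, vb)
                    rows.append((ga, gb, float(np.median(va)), float(np.median(vb)), p))
            bundle.figs2_table = pd.DataFrame(
                rows, columns=["age_a", "age_b", "median_a", "median_b", "p"]
            )
            # regression fits on the binned series
            if bundle.bin_series_by_age:
                bundle.slope_fits = st.fit_rsa_age_model(
                    bundle.bin_series_by_age, formula="dN~RSA"
                )
                bundle.interaction_fits = st.fit_rsa_age_model(
                    bundle.bin_series_by_age, formula="dN~RSA+RSA*age+age"
                )
                bundle.pearson_by_age = {
                    age: st.pearson_binned_correlation(s)
                    for age, s in bundle.bin_series_by_age.items()
                }
            # Table 1 analogue
            if category_rates is not None:
                rows = []
                for cat in SS_CATEGORIES + EXPOSURE_CATEGORIES:
                    sub = category_rates[category_rates.category == cat]
                    for ga, gb in _pairwise(age_names):
                        entry = {"category": cat, "age_pair": f"{ga}-{gb}"}
                        for metric in ("omega", "dn"):
                            va = sub.loc[sub.age_class == ga, metric].dropna().to_numpy()
                            vb = sub.loc[sub.age_class == gb, metric].dropna().to_numpy()
                            if len(va) and len(vb):
                                _, p = st.wilcoxon_test(va, vb)
                            else:
                                p = np.nan
                            entry[f"p_{metric}"] = p
                        rows.append(entry)
                bundle.table1 = pd.DataFrame(rows)
            status["stats"] = "ok"
        except Exception as exc:
            log.exception("stats stage failed")
            status["stats"] = f"failed: {exc}"
    else:
        status["stats"] = "disabled" if not enabled["stats"] else "skipped: no data"

    # ---- manifest and emission -----------------------------------------
    bundle.manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": config.config_hash(),
        "ages": age_names,
        "n_structures_per_age": config.n_structures_per_age,
        "n_codons_per_bin": config.n_codons_per_bin,
        "status": dict(status),
    }
    if config.outdir is not None:
        _emit(bundle, config)
    return bundle


def _emit(bundle: ReportBundle, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "structures.tsv": bundle.structure_table,
        "features.tsv": bundle.feature_table,
        "ages.tsv": bundle.age_table,
        "fig1_bins.tsv": bundle.fig1_table,
        "fig2_fraction_exposed.tsv": bundle.fig2_table,
        "figS2_omega.tsv": bundle.figs2_table,
        "fig3_robustness.tsv": bundle.fig3_table,
        "table1_category_age.tsv": bundle.table1,
        "stability_pairing.tsv": bundle.stability_pairing,
    }
    for name, table in tables.items():
        if table is not None:
            table.to_csv(outdir / name, sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    if config.make_plots and bundle.fig1_table is not None:
        _plot(bundle, outdir)


def _plot(bundle: ReportBundle, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for age, series in bundle.bin_series_by_age.items():
        ax.errorbar(series.bin_mid, series.dn, yerr=series.dn_se, label=age, marker="o", ms=3)
    ax.set_xlabel("RSA bin midpoint")
    ax.set_ylabel("dN")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig1_dn_vs_rsa.png", dpi=120)
    plt.close(fig)

    if bundle.structure_table is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        stbl = bundle.structure_table
        ages = sorted(stbl.age_class.unique())
        data = [stbl.loc[stbl.age_class == a, "fraction_exposed"] for a in ages]
        ax.boxplot(data, tick_labels=ages)
        ax.set_ylabel("% residues exposed")
        fig.tight_layout()
        fig.savefig(outdir / "fig2_fraction_exposed.png", dpi=120)
        plt.close(fig)

        if "rank" in stbl.columns:
            fig, ax = plt.subplots(figsize=(5, 4))
            data = [stbl.loc[stbl.age_class == a, "rank"].dropna() for a in ages]
            ax.boxplot(data, tick_labels=ages)
            ax.set_ylabel("native rank among mutants")
            fig.tight_layout()
            fig.savefig(outdir / "fig3_rank.png", dpi=120)
            plt.close(fig)
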