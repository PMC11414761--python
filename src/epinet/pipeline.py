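"""End-to-end orchestration of the epistasis analysis stages.

A run consumes a config mapping (or YAML file) naming the input files and
thresholds, executes the requested stages in dependency order —
fitness -> fitness epistasis, DE -> expression epistasis ->
classification -> coexpression network -> connectivity comparison — and
writes every table into the output directory stamped with the config hash
and seed.  Double-mutant genotypes are written "single+single" so pairing
with constituents is implicit in the label.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import compare as _compare
from . import de as _de
from . import epistasis as _epistasis
from . import expression as _expression
from . import fitness as _fitness
from . import network as _network

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

DEFAULTS = {
    "q_threshold": 0.001,
    "lfc_threshold": 2.0,
    "z_threshold": 2.0,
    "temperatures": [20.0, 37.0, 42.2],
    "stress_temperature": 42.2,
    "control_temperature": 37.0,
    "seed": 0,
    "network": {},
    "ppi_cutoff": 0.9,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(source: Mapping[str, Any] | str | pathlib.Path) -> dict:
    if isinstance(source, (str, pathlib.Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    merged = {**DEFAULTS, **cfg}
    for key in ("q_threshold", "lfc_threshold", "z_threshold"):
        if merged[key] <= 0:
            raise ValueError(f"{key} must be positive")
    for key in ("assays", "counts", "samples"):
        path = merged.get(key)
        if path is not None and not pathlib.Path(path).exists():
            raise FileNotFoundError(f"config {key}: {path} does not exist")
    return merged


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _mutant_contrasts(cm: _de.CountMatrix, config: Mapping[str, Any]) -> dict:
    """All contrast sample groupings the downstream stages need."""
    meta = cm.sample_meta
    hot = config["stress_temperature"]
    cool = config["control_temperature"]
    anc42 = list(meta[(meta["genotype"] == "ancestor") & (meta["temperature"] == hot)].index)
    anc37 = list(meta[(meta["genotype"] == "ancestor") & (meta["temperature"] == cool)].index)
    contrasts = {"anc42_vs_anc37": (anc37, anc42)}
    for g in meta["genotype"].unique():
        if g == "ancestor":
            continue
        samples = list(meta[(meta["genotype"] == g) & (meta["temperature"] == hot)].index)
        if len(samples) < 2:
            continue
        contrasts[f"{g}_vs_anc42"] = (anc42, samples)
        contrasts[f"{g}_vs_anc37"] = (anc37, samples)
    return contrasts


def run_pipeline(config, outdir, stages: set[str] | None = None) -> dict:
    """Execute the pipeline; returns the result bundle (also written to disk)."""
    config = load_config(config)
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    stamp = {"schema_version": SCHEMA_VERSION, "config_hash": chash,
             "seed": config["seed"]}
    bundle: dict[str, Any] = {"stamp": stamp, "complete": False}
    all_stages = {"fitness", "epistasis_fitness", "de", "epistasis_expression",
                  "classify", "network", "compare"}
    stages = all_stages if stages is None else set(stages)

    fitness_summary = None
    if "fitness" in stages and config.get("assays"):
        try:
            assays = _fitness.read_assay_table(config["assays"])
            estimates = _fitness.summarize_fitness(assays)
            fitness_summary = _fitness.summary_frame(estimates)
            fitness_summary.to_csv(out / "fitness_summary.tsv", sep="\t", index=False)
            bundle["fitness"] = fitness_summary
        except Exception as exc:  # noqa: BLE001
            raise StageError("fitness", str(exc)) from exc

    if "epistasis_fitness" in stages and fitness_summary is not None:
        try:
            bundle.update(_run_fitness_epistasis(fitness_summary, out))
        except Exception as exc:  # noqa: BLE001
            raise StageError("epistasis_fitness", str(exc)) from exc

    de_tables: dict[str, list] = {}
    cm = None
    if "de" in stages and config.get("counts"):
        try:
            cm = _de.read_count_matrix(config["counts"], config["samples"])
            if config.get("de_tables"):
                for cid, path in config["de_tables"].items():
                    de_tables[cid] = _de.ingest_de_table(path, cid, cm.genes)
            else:
                logger.info("no external DE tables; computing internally")
                factors = _de.size_factors(cm)
                normalized = _de.normalize(cm, factors)
                for cid, (ga, gb) in _mutant_contrasts(cm, config).items():
                    de_tables[cid] = _de.simple_de(normalized, ga, gb, cid)
            pd.concat([_de.records_frame(v) for v in de_tables.values()]).to_csv(
                out / "de_tables.tsv", sep="\t", index=False)
            bundle["de"] = de_tables
            bundle["normalized"] = _de.normalize(cm) if cm is not None else None
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("de", str(exc)) from exc

    if "epistasis_expression" in stages and de_tables:
        try:
            bundle.update(_run_expression_epistasis(de_tables, config, out))
            if config.get("gene_sets") and bundle.get("expression_tables"):
                bundle.update(_run_gene_sets(bundle["expression_tables"],
                                             config, out))
        except Exception as exc:  # noqa: BLE001
            raise StageError("epistasis_expression", str(exc)) from exc

    if "classify" in stages and de_tables:
        try:
            bundle.update(_run_classification(de_tables, config, out))
        except Exception as exc:  # noqa: BLE001
            raise StageError("classify", str(exc)) from exc

    if "network" in stages and cm is not None:
        try:
            expr = _network.transform_expression(bundle["normalized"])
            net_config = _network.NetworkConfig(**config.get("network", {}))
            state = _network.build_network(expr, net_config)
            module_table = pd.DataFrame({
                "gene": state.genes,
                "module": state.module_labels.values,
                "k_within": state.connectivity["k_within"].values,
                "k_total": state.connectivity["k_total"].values,
                "kME": state.kme["kme"].values,
                "kME_p": state.kme["kme_p"].values,
                "hub": state.hub_flags.values,
            })
            module_table.to_csv(out / "modules.tsv", sep="\t", index=False)
            state.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
            bundle["network"] = state
            if fitness_summary is not None:
                traits = _sample_traits(cm, fitness_summary, config)
                if traits is not None:
                    assoc = _network.module_trait_association(state.eigengenes,
                                                              traits)
                    assoc.to_csv(out / "module_trait.tsv", sep="\t", index=False)
                    bundle["module_trait"] = assoc
        except Exception as exc:  # noqa: BLE001
            raise StageError("network", str(exc)) from exc

    if "compare" in stages and bundle.get("network") is not None \
            and bundle.get("expression_tables"):
        try:
            bundle.update(_run_comparison(bundle, config, out))
        except Exception as exc:  # noqa: BLE001
            raise StageError("compare", str(exc)) from exc

    bundle["complete"] = True
    with open(out / "run_stamp.json", "w") as fh:
        json.dump(stamp, fh)
    return bundle


def _run_fitness_epistasis(summary: pd.DataFrame, out: pathlib.Path) -> dict:
    by_key = {(r.genotype_id, r.temperature): _fitness.RelativeFitnessEstimate(
        r.genotype_id, r.temperature, r.w_bar, r.variance, int(r.n),
        r.t_vs_one, r.p_raw, r.p_bonferroni) for r in summary.itertuples(index=False)}
    estimates = []
    pairs = []
    for (gid, temp), est in by_key.items():
        if "+" not in gid:
            continue
        rho, rpob = gid.split("+", 1)
        wx = by_key.get((rho, temp))
        wy = by_key.get((rpob, temp))
        if wx is None or wy is None:
            continue
        estimates.append(_epistasis.epistatic_deviation(wx, wy, est))
        pairs.append({"temperature": temp, "foreground_allele": rpob,
                      "w_background": wx.w_bar, "w_double": est.w_bar})
    eps_frame = _epistasis.epistasis_frame(estimates)
    eps_frame.to_csv(out / "fitness_epistasis.tsv", sep="\t", index=False)
    pooled = []
    groups: dict[float, list[float]] = {}
    for est in estimates:
        groups.setdefault(est.temperature, []).append(est.epsilon)
    for temp, vals in groups.items():
        if len(vals) >= 2:
            pooled.append(_epistasis.pooled_epistasis(vals, temp))
    pooled_frame = pd.DataFrame([vars(p) for p in pooled])
    pooled_frame.to_csv(out / "pooled_epistasis.tsv", sep="\t", index=False)
    anova = None
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        anova = _epistasis.epistasis_anova(groups)
    dr = _epistasis.diminishing_returns(pd.DataFrame(pairs)) if pairs else []
    pd.DataFrame([vars(f) for f in dr]).to_csv(
        out / "diminishing_returns.tsv", sep="\t", index=False)
    return {"fitness_epistasis": eps_frame, "pooled_epistasis": pooled_frame,
            "epistasis_anova": anova, "diminishing_returns": dr}


def _run_expression_epistasis(de_tables, config, out: pathlib.Path) -> dict:
    doubles = sorted({cid[:-len("_vs_anc42")] for cid in de_tables
                      if cid.endswith("_vs_anc42") and "+" in cid})
    tables = {}
    moments_out = {}
    for d in doubles:
        rho, rpob = d.split("+", 1)
        cx, cy, cxy = f"{rho}_vs_anc42", f"{rpob}_vs_anc42", f"{d}_vs_anc42"
        if cx not in de_tables or cy not in de_tables:
            logger.warning("skipping %s: missing single-mutant contrasts", d)
            continue
        table = _expression.build_epistasis_table(
            de_tables[cx], de_tables[cy], de_tables[cxy], d)
        table = _expression.flag_significant(
            table, {c: de_tables[c] for c in (cx, cy, cxy)},
            q_threshold=config["q_threshold"],
            lfc_threshold=config["lfc_threshold"],
            z_threshold=config["z_threshold"])
        tables[d] = table
        moments_out[d] = vars(_expression.moments(table["epsilon_exp"], d))
    if tables:
        pd.concat(tables.values()).to_csv(out / "expression_epistasis.tsv",
                                          sep="\t", index=False)
        with open(out / "moments.json", "w") as fh:
            json.dump(moments_out, fh, indent=1)
    return {"expression_tables": tables, "moments": moments_out}


def _run_classification(de_tables, config, out: pathlib.Path) -> dict:
    if "anc42_vs_anc37" not in de_tables:
        raise ValueError("classification needs the anc42_vs_anc37 contrast")
    mutants = sorted({cid[:-len("_vs_anc42")] for cid in de_tables
                      if cid.endswith("_vs_anc42")})
    calls = []
    for m in mutants:
        c42, c37 = f"{m}_vs_anc42", f"{m}_vs_anc37"
        if c37 not in de_tables:
            continue
        calls.extend(_classify.classify_mutant(
            de_tables["anc42_vs_anc37"], de_tables[c42], de_tables[c37],
            m, config["q_threshold"]))
    if not calls:
        return {"classification": None}
    doubles = [m for m in mutants if "+" in m]
    groups = {"all_doubles": doubles} if doubles else None
    counts, report = _classify.classification_table(calls, groups)
    counts.to_csv(out / "classification_counts.tsv", sep="\t")
    with open(out / "classification_intersections.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return {"classification": counts, "classification_report": report}


def _run_gene_sets(tables, config, out: pathlib.Path) -> dict:
    from . import expression as _expr

    sets: dict[str, list[str]] = {}
    paths = config["gene_sets"]
    for path in ([paths] if isinstance(paths, str) else paths):
        sets.update(_expr.read_gene_set(path))
    rows = []
    for d, table in tables.items():
        for name, members in sets.items():
            try:
                rows.append(vars(_expr.geneset_summary(table, members, name)))
            except ValueError as exc:
                logger.warning("gene set %s x %s skipped: %s", name, d, exc)
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "gene_set_summary.tsv", sep="\t", index=False)
    return {"gene_set_summary": frame}


def _sample_traits(cm, fitness_summary: pd.DataFrame, config) -> pd.DataFrame | None:
    """Per-sample relative-fitness traits: each sample inherits its
    genotype's w̄ at each assay temperature."""
    by_key = {(r.genotype_id, r.temperature): r.w_bar
              for r in fitness_summary.itertuples(index=False)}
    temps = sorted({T for (_, T) in by_key})
    if not temps:
        return None
    data = {}
    for T in temps:
        # the ancestor is the competition reference: w = 1 by definition
        col = [1.0 if g == "ancestor" else by_key.get((g, T), np.nan)
               for g in cm.sample_meta["genotype"]]
        data[f"w_{T}C"] = col
    traits = pd.DataFrame(data, index=cm.sample_meta.index)
    traits = traits.dropna(axis=1, how="any")
    return traits if not traits.empty else None


def _run_comparison(bundle, config, out: pathlib.Path) -> dict:
    state = bundle["network"]
    tables = bundle["expression_tables"]
    sig = pd.Series(False, index=state.module_labels.index)
    for table in tables.values():
        flagged = table.loc[table["tier_b"], "gene"]
        sig.loc[sig.index.intersection(flagged)] = True
    k_total = state.connectivity["k_total"]
    if not sig.any() or sig.all():
        result = {"coexpression": {
            "note": "not-applicable: epistatic or non-epistatic group empty"}}
        with open(out / "connectivity_comparison.json", "w") as fh:
            json.dump(result, fh, indent=1)
        return {"comparison": result}
    coexp = _compare.compare_connectivity(k_total, sig)
    result = {"coexpression": vars(coexp)}
    if config.get("ppi_edges"):
        edges = _compare.read_ppi_edges(config["ppi_edges"])
        degrees = _compare.ppi_degrees(edges, config["ppi_cutoff"],
                                       gene_universe=sig.index)
        result["ppi"] = vars(_compare.compare_connectivity(degrees, sig))
        hubs = state.hub_flags
        if sig.any():
            odds, p, table = _compare.hub_enrichment(
                sig[sig].index, hubs, gene_universe=sig.index)
            result["hub_enrichment"] = {"odds_ratio": odds, "p": p,
                                        "table": table.tolist()}
    with open(out / "connectivity_comparison.json", "w") as fh:
        json.dump(result, fh, indent=1)
    return {"comparison": result}


def report(bundle: Mapping[str, Any], out_path) -> dict:
    """Machine-readable summary of a completed (or partial) run."""
    doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION,
                           "stamp": bundle.get("stamp"),
                           "complete": bool(bundle.get("complete"))}
    if not bundle.get("complete"):
        doc["partial"] = True
    eps = bundle.get("fitness_epistasis")
    if eps is not None and len(eps):
        doc["fitness_epistasis"] = eps.to_dict(orient="records")
    pooled = bundle.get("pooled_epistasis")
    if pooled is not None and len(pooled):
        doc["pooled_epistasis"] = pooled.to_dict(orient="records")
    if bundle.get("epistasis_anova") is not None:
        F, df, p = bundle["epistasis_anova"]
        doc["epistasis_anova"] = {"F": F, "df": list(df), "p": p}
    tables = bundle.get("expression_tables") or {}
    tier_counts = {}
    sign_tests = {}
    for d, table in tables.items():
        tier_counts[d] = {"tier_a": int(table["tier_a"].sum()),
                          "tier_b": int(table["tier_b"].sum())}
        flagged = table[table["tier_b"]]
        if len(flagged):
            p, npos, nneg = _expression.sign_balance(flagged["epsilon_exp"])
            sign_tests[d] = {"p": p, "n_pos": npos, "n_neg": nneg}
        else:
            sign_tests[d] = {"p": None, "note": "not-applicable: no flagged genes"}
    if tier_counts:
        doc["tier_counts"] = tier_counts
        doc["sign_tests"] = sign_tests
    if bundle.get("moments"):
        doc["moments"] = bundle["moments"]
    state = bundle.get("network")
    if state is not None:
        module_rows = []
        for module, members in state.module_labels.groupby(state.module_labels):
            if module == "grey":
                continue
            idx = members.index
            module_rows.append({
                "module": module, "n_genes": int(len(idx)),
                "n_hubs": int(state.hub_flags.loc[idx].sum()),
                "mean_k_within": float(state.connectivity.loc[idx, "k_within"].mean()),
            })
        doc["modules"] = module_rows
    if bundle.get("comparison"):
        doc["connectivity_comparison"] = bundle["comparison"]
    with open(out_path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
    return doc
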