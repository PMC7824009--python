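"""End-to-end orchestration of the panel-reduction pipeline.

Stages: read + consistency checks -> SNP filters (missingness, probe
identity, MAF) -> diploidize -> windowed LD pruning to one subset per
requested threshold or target size -> mixed-model GWAS per trait per subset
-> Bayesian prediction grid with LOO-CV. Every stage writes a plain-text
artifact so any stage can be rerun standalone, and a marker-count audit
trail records the filter chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import gwas as tgwas
from . import ldprune, prediction
from .errors import PipelineStageError, TetrapanelError


def _default_models():
    return list(tgwas.GENE_ACTION_MODELS)


def _default_priors():
    return list(prediction.PRIOR_NAMES)


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults follow the standard study protocol."""

    genotypes: str = ""
    marker_map: str = ""
    phenotypes: str = ""
    identity: str = ""
    metadata: str = ""
    out_dir: str = "pipeline_out"

    max_missing: int = 10
    min_pident: float = 97.0
    min_maf: float = 0.05

    window_snps: int = 50
    step_snps: int = 10
    r2_thresholds: list = field(default_factory=list)
    target_sizes: list = field(default_factory=list)

    n_pcs: int = 2
    gwas_models: list = field(default_factory=_default_models)
    alpha: float = 0.05
    gwas_traits: list = field(default_factory=lambda: [
        "tuber_number", "tuber_weight_total", "audpc", "flowering_days"])

    priors: list = field(default_factory=_default_priors)
    prediction_traits: list = field(default_factory=lambda: [
        "tuber_number", "audpc"])
    family_flags: tuple = (False, True)
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    run_gwas: bool = True
    run_prediction: bool = True

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "family_flags" in raw:
            raw["family_flags"] = tuple(raw["family_flags"])
        return PipelineConfig(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns the report dict (also written as
    YAML)."""
    if not (cfg.r2_thresholds or cfg.target_sizes):
        raise ValueError(
            "config must list at least one r2 threshold or target size"
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "parameters": asdict(cfg)}

    def stage(name, fn):
        try:
            result = fn()
        except TetrapanelError as e:
            raise PipelineStageError(name, e) from e
        report["stages"].append(name)
        return result

    # ---- read and check inputs -------------------------------------------
    def read_inputs():
        g = tio.read_genotypes(cfg.genotypes)
        mm = tio.read_marker_map(cfg.marker_map)
        ph = tio.read_phenotypes(cfg.phenotypes)
        ident = tio.read_identity_table(cfg.identity) if cfg.identity else None
        meta = tio.read_sample_metadata(cfg.metadata) if cfg.metadata else None
        unmapped = set(g.marker_ids) - set(mm["marker"])
        if unmapped:
            raise TetrapanelError(
                f"{len(unmapped)} genotyped markers absent from the map "
                f"(e.g. {sorted(unmapped)[:3]})"
            )
        missing_ph = set(g.sample_ids) - set(ph["sample_id"])
        if missing_ph:
            raise TetrapanelError(
                f"{len(missing_ph)} genotyped samples lack phenotypes "
                f"(e.g. {sorted(missing_ph)[:3]})"
            )
        return g, mm, ph, ident, meta

    g, mm, ph, ident, meta = stage("read-inputs", read_inputs)
    audit = [("input", g.n_markers)]

    # ---- filters ----------------------------------------------------------
    def filters():
        g1 = tio.filter_missingness(g, cfg.max_missing)
        audit.append(("post-missingness", g1.n_markers))
        if ident is not None:
            g1 = tio.filter_identity(g1, ident, cfg.min_pident)
        audit.append(("post-identity", g1.n_markers))
        g1 = tio.filter_maf(g1, cfg.min_maf)
        audit.append(("post-maf", g1.n_markers))
        return g1

    gf = stage("snp-filters", filters)
    maf_tetra = tio.maf(gf)

    # ---- diploidize + prune ----------------------------------------------
    def prune():
        dip = tio.diploidize(gf)
        subsets = []
        for thr in cfg.r2_thresholds:
            params = ldprune.PruneParams(cfg.window_snps, cfg.step_snps,
                                         float(thr))
            subsets.append(ldprune.prune_genome(dip, mm, params, maf_tetra))
        for tgt in cfg.target_sizes:
            _, sub = ldprune.subset_for_target_size(
                dip, mm, int(tgt), cfg.window_snps, cfg.step_snps,
                maf_for_ties=maf_tetra,
            )
            subsets.append(sub)
        subsets.sort(key=lambda s: s.size)
        for sub in subsets:
            sub.write(out / f"subset_{sub.size}.txt")
            audit.append((f"subset-r2={sub.params.r2_threshold:.3f}",
                          sub.size))
        return subsets

    subsets = stage("ld-prune", prune)
    pd.DataFrame(audit, columns=["stage", "n_markers"]).to_csv(
        out / "marker_audit.tsv", sep="\t", index=False
    )
    report["marker_audit"] = audit

    ph_idx = ph.set_index("sample_id").loc[gf.sample_ids]

    # ---- GWAS -------------------------------------------------------------
    if cfg.run_gwas:
        def run_gwas():
            rows = []
            for sub in subsets:
                gsub = gf.subset_markers(sub.retained_marker_ids)
                K = tgwas.kinship(gsub)
                for trait in cfg.gwas_traits:
                    y = ph_idx[trait].to_numpy(dtype=float)
                    keep = np.isfinite(y)
                    gt = gsub.subset_samples(
                        [s for s, k in zip(gsub.sample_ids, keep) if k]
                    )
                    res = tgwas.gwas_scan(
                        y[keep], gt, K[np.ix_(keep, keep)],
                        n_pcs=cfg.n_pcs, models=cfg.gwas_models,
                        alpha=cfg.alpha,
                    )
                    nq = tgwas.count_qtl(res)
                    rows.append({
                        "subset_size": sub.size, "trait": trait,
                        "n_qtl": nq,
                        "qtl_per_snp": tgwas.qtl_per_snp(nq, sub.size),
                        "threshold": res.threshold,
                    })
            return pd.DataFrame(rows)

        qtl_table = stage("gwas", run_gwas)
        qtl_table.to_csv(out / "qtl_counts.tsv", sep="\t", index=False)
        report["qtl_counts"] = qtl_table.to_dict("records")

    # ---- prediction grid --------------------------------------------------
    if cfg.run_prediction:
        def run_prediction():
            if meta is not None:
                offspring = meta.loc[meta["role"] == "offspring",
                                     "sample_id"]
                keep_ids = [s for s in gf.sample_ids
                            if s in set(offspring)]
            else:
                keep_ids = list(gf.sample_ids)
            gp = gf.subset_samples(keep_ids)
            php = ph.set_index("sample_id").loc[keep_ids]
            fams = pd.get_dummies(php["family"], drop_first=True)
            X = fams.to_numpy(dtype=float)
            Z = gp.dosages.copy()
            mu = np.nanmean(Z, axis=0)
            nanmask = np.isnan(Z)
            Z[nanmask] = np.take(mu, np.nonzero(nanmask)[1])
            traits = {}
            for t in cfg.prediction_traits:
                y = php[t].to_numpy(dtype=float)
                if np.isfinite(y).all():
                    traits[t] = y
            chain = prediction.ChainSettings(cfg.n_iter, cfg.burn_in,
                                             cfg.thin, cfg.seed)
            return prediction.grid_evaluate(
                traits, Z, gp.marker_ids, subsets, X,
                priors=cfg.priors, family_flags=cfg.family_flags,
                chain=chain,
            )

        acc_table = stage("prediction", run_prediction)
        acc_table.to_csv(out / "accuracy_grid.tsv", sep="\t", index=False)
        report["accuracy_grid"] = acc_table.to_dict("records")

    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(report), fh, sort_keys=False)
    return report


def _yamlable(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
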