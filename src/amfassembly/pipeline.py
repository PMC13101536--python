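"""End-to-end orchestration of the community-assembly analysis.

Stage order: ingest -> niche classification -> group split
(all / generalists / specialists) -> per-group βNTI + assembly fractions
and NCM fits -> pollution indices -> diversity / Bray-Curtis / Mantel /
Spearman / βNTI~Pn regression -> Venn partition -> run manifest.

Reproducibility: one global seed; each stochastic stage draws a sub-seed
from a stable CRC32 hash of (stage name, global seed), so reordering
stages cannot change any stage's stream.  A rerun with the same config
produces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community_io as cio
from . import eco_stats, neutral_model, niche_classifier, phylo_turnover, pollution_index

logger = logging.getLogger("amfassembly")

GROUPS = ("all", "generalists", "specialists")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs remain."""


@dataclass
class PipelineConfig:
    table_path: str
    tree_path: str
    metadata_path: str
    backgrounds_path: str
    out_dir: str
    orientation: str = "samples_as_rows"
    n_perm_niche: int = 1000
    n_null_bnti: int = 999
    detection_reads: int = 1
    alpha: float = 0.05
    seed: int = 0
    pairing: str = "pair_mean"
    niche_null_model: str = "margins"
    weighted_bmntd: bool = True
    make_plots: bool = False

    def validate(self) -> None:
        for name in ("n_perm_niche", "n_null_bnti", "detection_reads"):
            if getattr(self, name) < 1:
                raise cio.ConfigError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise cio.ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a YAML or JSON config file."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def derive_seed(stage: str, global_seed: int) -> int:
    """Stable per-stage sub-seed (CRC32 of stage name + global seed)."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def _pair_frame(bnti_results, meta_df: pd.DataFrame, columns) -> pd.DataFrame:
    """Per-pair means of per-sample covariates, aligned with βNTI pairs."""
    rows = []
    for r in bnti_results:
        if r.degenerate:
            continue
        row = {"bnti": r.bnti}
        for c in columns:
            row[c] = (meta_df.loc[r.sample_a, c] + meta_df.loc[r.sample_b, c]) / 2.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a summary dict and writes artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "pipeline.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    summary: dict = {}
    try:
        with _stage("ingest"):
            table = cio.read_otu_table(config.table_path, config.orientation)
            tree = cio.read_tree(config.tree_path, missing_lengths="zero")
            records = cio.read_metadata(config.metadata_path)
            backgrounds = cio.read_backgrounds(config.backgrounds_path)
            table, records = cio.align(table, records)
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            missing = set(table.otu_ids) - tips
            if missing:
                raise ValueError(
                    f"{len(missing)} table OTU(s) absent from tree (βNTI prerequisite)"
                )
            meta_df = cio.metadata_frame(records)

        with _stage("niche_classification"):
            niche = niche_classifier.classify_otus(
                table, n_perm=config.n_perm_niche, alpha=config.alpha,
                seed=derive_seed("niche", config.seed),
                null_model=config.niche_null_model,
            )
            niche_df = niche_classifier.classification_frame(niche)
            niche_df.to_csv(out / "niche_labels.tsv", sep="\t")
            labels = niche_classifier.labels_dict(niche)
            summary["niche_counts"] = niche_df.label.value_counts().to_dict()

        with _stage("group_split"):
            group_tables = {"all": table}
            for grp, lbl in (("generalists", "generalist"), ("specialists", "specialist")):
                ids = [o for o in table.otu_ids if labels[o] == lbl]
                if len(ids) < 2:
                    logger.warning("group %s has %d OTU(s); skipped", grp, len(ids))
                    continue
                sub = table.subset_otus(ids)
                empty = sub.sample_totals() == 0
                if empty.any():
                    keep = [s for s, e in zip(sub.sample_ids, empty) if not e]
                    logger.warning(
                        "group %s: dropping %d sample(s) emptied by subsetting",
                        grp, int(empty.sum()),
                    )
                    sub = sub.subset_samples(keep)
                group_tables[grp] = sub

        with _stage("phylogenetic_turnover"):
            d_labels, dmat = phylo_turnover.patristic_distances(tree)
            bnti_results = {}
            fractions = {}
            for grp, gtable in group_tables.items():
                res = phylo_turnover.beta_nti(
                    gtable, d_labels, dmat, n_null=config.n_null_bnti,
                    weighted=config.weighted_bmntd,
                    seed=derive_seed(f"bnti:{grp}", config.seed),
                )
                bnti_results[grp] = res
                phylo_turnover.bnti_frame(res).to_csv(
                    out / f"bnti_{grp}.tsv", sep="\t", index=False
                )
                try:
                    fractions[grp] = phylo_turnover.assembly_fractions(res)
                except ValueError as exc:
                    # e.g. every sample shares the identical OTU set: no
                    # phylogenetic turnover, fractions undefined
                    logger.warning("assembly fractions undefined for group %s: %s", grp, exc)
                    fractions[grp] = None
            _write_json(fractions, out / "assembly_fractions.json")
            summary["assembly_fractions"] = fractions

        with _stage("neutral_model"):
            fits = {}
            for grp, gtable in group_tables.items():
                try:
                    fit = neutral_model.fit_ncm(gtable, d_reads=config.detection_reads)
                except (ValueError, neutral_model.FitError) as exc:
                    logger.warning("NCM fit skipped for group %s: %s", grp, exc)
                    continue
                fits[grp] = fit
                fit.per_otu.to_csv(out / f"ncm_per_otu_{grp}.tsv", sep="\t", index=False)
            _write_json({g: f.summary() for g, f in fits.items()}, out / "ncm_fits.json")
            if len(fits) >= 2:
                neutral_model.compare_group_fits(fits).to_csv(
                    out / "ncm_comparison.tsv", sep="\t", index=False
                )
            summary["ncm"] = {g: f.summary() for g, f in fits.items()}

        with _stage("pollution"):
            poll = pollution_index.compute_pollution(records, backgrounds)
            pollution_index.pollution_frame(poll).to_csv(out / "pollution.tsv", sep="\t")
            summary["mean_pn"] = float(np.mean([p.pn for p in poll]))
            summary["fraction_polluted"] = float(np.mean([p.polluted for p in poll]))

        with _stage("diversity"):
            div = eco_stats.alpha_diversity(table)
            eco_stats.diversity_frame(div).to_csv(out / "diversity.tsv", sep="\t")
            bc = eco_stats.bray_curtis(table)
            pd.DataFrame(bc, index=table.sample_ids, columns=table.sample_ids).to_csv(
                out / "bray_curtis.tsv", sep="\t"
            )

        with _stage("mantel"):
            mantel_out = {}
            for metal in cio.METALS:
                vals = meta_df.loc[table.sample_ids, metal].to_numpy(float)[:, None]
                env_d = np.abs(vals - vals.T)  # Euclidean distance on one variable
                res = eco_stats.mantel_test(
                    bc, env_d, n_perm=999,
                    seed=derive_seed(f"mantel:{metal}", config.seed),
                )
                mantel_out[metal] = {
                    "r": res.r, "p_value": res.p_value,
                    "stars": eco_stats.significance_stars(res.p_value),
                }
            _write_json(mantel_out, out / "mantel.json")
            summary["mantel"] = mantel_out

        with _stage("correlations"):
            rows = []
            for grp, res in bnti_results.items():
                pair_df = _pair_frame(res, meta_df, cio.METALS)
                if len(pair_df) < 4:
                    continue
                rho, pv = eco_stats.spearman_matrix(
                    pair_df[list(cio.METALS)], pair_df[["bnti"]]
                )
                for metal in cio.METALS:
                    rows.append({
                        "group": grp, "metal": metal,
                        "rho": rho.loc[metal, "bnti"], "p_value": pv.loc[metal, "bnti"],
                        "stars": eco_stats.significance_stars(pv.loc[metal, "bnti"]),
                    })
            pd.DataFrame(rows).to_csv(out / "correlations.tsv", sep="\t", index=False)

        with _stage("regression"):
            reg_out = {}
            for grp, res in bnti_results.items():
                try:
                    reg = eco_stats.bnti_vs_pollution(res, poll, pairing=config.pairing)
                except ValueError as exc:
                    logger.warning("regression skipped for group %s: %s", grp, exc)
                    continue
                reg_out[grp] = {
                    "slope": reg.slope, "intercept": reg.intercept,
                    "r_squared": reg.r_squared, "p_value": reg.p_value,
                    "n_pairs": reg.n, "pairing": config.pairing,
                    "stars": eco_stats.significance_stars(reg.p_value),
                }
            _write_json(reg_out, out / "regression.json")
            summary["regression"] = reg_out

        with _stage("venn"):
            venn = eco_stats.shared_otu_partition(table, records)
            _write_json(venn, out / "venn.json")
            summary["venn"] = venn

        if config.make_plots:
            with _stage("plots"):
                _diagnostic_plots(out, fits, reg_out, bnti_results, poll, config)

        with _stage("manifest"):
            manifest = {
                "config": asdict(config),
                "seed": config.seed,
                "package": "amfassembly",
                "inputs_sha256": {
                    "table": _sha256(config.table_path),
                    "tree": _sha256(config.tree_path),
                    "metadata": _sha256(config.metadata_path),
                    "backgrounds": _sha256(config.backgrounds_path),
                },
                "groups": sorted(group_tables),
            }
            _write_json(manifest, out / "manifest.json")
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return summary


def _diagnostic_plots(out, fits, reg_out, bnti_results, poll, config) -> None:
    """NCM occurrence-frequency curve and βNTI~Pn scatter (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "all" in fits:
        fit = fits["all"]
        df = fit.per_otu.sort_values("p")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(np.log10(df.p), df.observed_freq, s=8, alpha=0.6)
        ax.plot(np.log10(df.p), df.predicted_freq, color="C0")
        ax.plot(np.log10(df.p), df.lower95, "--", color="C0")
        ax.plot(np.log10(df.p), df.upper95, "--", color="C0")
        ax.set_xlabel("log10 mean relative abundance")
        ax.set_ylabel("occurrence frequency")
        ax.set_title(f"NCM fit: m={fit.m:.3f}, R2={fit.r_squared:.3f}")
        fig.tight_layout()
        fig.savefig(out / "ncm_curve_all.png", dpi=100)
        plt.close(fig)

    if "all" in bnti_results:
        pn = {p.sample_id: p.pn for p in poll}
        xs, ys = [], []
        for r in bnti_results["all"]:
            if r.degenerate:
                continue
            xs.append((pn[r.sample_a] + pn[r.sample_b]) / 2.0
                      if config.pairing == "pair_mean"
                      else abs(pn[r.sample_a] - pn[r.sample_b]))
            ys.append(r.bnti)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(xs, ys, s=8, alpha=0.6)
        ax.axhline(2, ls="--", c="gray")
        ax.axhline(-2, ls="--", c="gray")
        ax.set_xlabel("pairwise Pn")
        ax.set_ylabel("βNTI")
        fig.tight_layout()
        fig.savefig(out / "bnti_vs_pn_all.png", dpi=100)
        plt.close(fig)
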