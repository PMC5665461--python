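"""Heatmap-style clustering, MA-plot data products, and pipeline orchestration.

Clustering follows the heatmap convention used for the study's expression
figures: rows are z-score normalized, then rows and/or columns are
agglomeratively clustered on Pearson-correlation distance (1 - r) with
average linkage by default.  Every figure has a TSV twin so downstream
checks never parse images.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from . import preprocess, differential, rif as rif_mod, genesets, simulate, io as mio
from .differential import DiffTable

logger = logging.getLogger(__name__)


def row_zscore(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Rescale each row to mean 0, sd 1 over its present cells.

    Zero-variance rows are left at 0 and listed in
    ``result.attrs['degenerate_rows']``.  Idempotent up to floating
    tolerance.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    flat = sd.isna() | (sd < 1e-12)
    out = matrix.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    out.loc[flat] = out.loc[flat].where(matrix.loc[flat].isna(), 0.0)
    out.attrs["degenerate_rows"] = matrix.index[flat].tolist()
    return out


@dataclass
class ClusterResult:
    """Dendrogram orders plus the merge record for one clustering run."""

    row_ids: list
    row_order: list                      # permutation of row_ids, leaf order
    row_linkage: np.ndarray | None
    col_ids: list | None = None
    col_order: list | None = None
    col_linkage: np.ndarray | None = None
    metric: str = "pearson"
    method: str = "average"
    normalization: str = "row-zscore"

    def cut_rows(self, k: int) -> pd.Series:
        return self._cut(self.row_linkage, self.row_ids, k)

    def cut_cols(self, k: int) -> pd.Series:
        if self.col_linkage is None:
            raise ValueError("columns were not clustered")
        return self._cut(self.col_linkage, self.col_ids, k)

    @staticmethod
    def _cut(Z, ids, k) -> pd.Series:
        return pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=ids)


def _pairwise_distance(X: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distances; missing cells use pairwise-complete observations."""
    if not np.isnan(X).any():
        if metric == "pearson":
            return pdist(X, metric="correlation")
        return pdist(X, metric="euclidean")
    n = len(X)
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if mask.sum() < 2:
                raise ValueError(
                    f"rows {i} and {j} share fewer than 2 observed cells")
            x, y = X[i, mask], X[j, mask]
            if metric == "pearson":
                sx, sy = x.std(), y.std()
                if sx < 1e-12 or sy < 1e-12:
                    out[idx] = 1.0  # no correlation signal
                else:
                    out[idx] = 1.0 - np.corrcoef(x, y)[0, 1]
            else:
                out[idx] = float(np.sqrt(((x - y) ** 2).sum()))
            idx += 1
    return out


def hcluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    distance: str = "pearson",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows, columns or both.

    Deterministic for a given input (ties resolve by input order).  With
    missing cells distances use pairwise-complete observations; a pair
    sharing fewer than 2 cells is an error.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"axis must be rows/columns/both, got {axis!r}")
    if distance not in ("pearson", "euclidean"):
        raise ValueError(f"distance must be pearson/euclidean, got {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"linkage must be average/complete, got {linkage!r}")

    def one_axis(X, ids):
        if len(ids) < 2:
            raise ValueError("need at least 2 items to cluster")
        Z = scipy_linkage(_pairwise_distance(X, distance), method=linkage)
        order = [ids[i] for i in leaves_list(Z)]
        return Z, order

    result = ClusterResult(row_ids=list(matrix.index), row_order=list(matrix.index),
                           row_linkage=None, metric=distance, method=linkage)
    if axis in ("rows", "both"):
        Z, order = one_axis(matrix.to_numpy(dtype=float), list(matrix.index))
        result.row_linkage, result.row_order = Z, order
    if axis in ("columns", "both"):
        Z, order = one_axis(matrix.to_numpy(dtype=float).T, list(matrix.columns))
        result.col_ids = list(matrix.columns)
        result.col_linkage, result.col_order = Z, order
    return result


def ma_plot_data(
    diff: DiffTable,
    stage: int,
    threshold: float = differential.DEFAULT_MA_THRESHOLD,
    highlight: dict[str, "genesets.GeneSet"] | None = None,
) -> pd.DataFrame:
    """(a, d, pif) rows passing the MA filter at one stage, with set flags.

    Each entry of ``highlight`` adds a boolean membership column named
    ``in_{set name}``; a set with no member among the plotted rows keeps an
    all-False column and logs a warning.
    """
    keep = differential.ma_filter(diff, stage, threshold)
    out = pd.DataFrame({"a": diff.a.loc[keep, stage], "d": diff.d.loc[keep, stage],
                        "pif": diff.pif.loc[keep, stage]})
    for name, gset in (highlight or {}).items():
        symbols = genesets._symbols_of(out.index)
        col = symbols.isin(set(gset.genes))
        if not col.any():
            logger.warning("ma_plot_data: highlight set %r absent from stage %s rows",
                           name, stage)
        out[f"in_{name}"] = np.asarray(col)
    return out


def plot_ma(ma_data: pd.DataFrame, stage: int, path: str | Path) -> Path:
    """Render the MA scatter (abundance vs contrast) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ma_data["a"], ma_data["d"], s=6, c="0.6", linewidths=0)
    for col in [c for c in ma_data.columns if c.startswith("in_")]:
        sel = ma_data[ma_data[col]]
        ax.scatter(sel["a"], sel["d"], s=12, label=col[3:], linewidths=0)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("average abundance a (log2)")
    ax.set_ylabel("DE d = BA - CH (log2)")
    ax.set_title(f"{stage} dpc")
    if any(c.startswith("in_") for c in ma_data.columns):
        ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# pipeline orchestration


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute preprocess -> differential -> rif -> genesets -> report.

    ``config`` is a dict (or YAML/JSON path) with either a ``simulate``
    section (keyword overrides for :class:`simulate.SimulationConfig`) or an
    ``inputs`` section naming matrix/design/probe_map (and optionally
    regulator/mito gene-set) files, plus an optional ``params`` section.
    Writes TSV artifacts, figures, a JSON summary of headline statistics and
    a log into the output directory; returns the directory.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "musclenet_out"))
    out.mkdir(parents=True, exist_ok=True)
    params = {**_DEFAULT_PARAMS, **cfg.get("params", {})}

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("musclenet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"params": params}
    try:
        stage_name = "inputs"
        matrix, design, probe_map, regulator_list, mito_set, truth = _load_inputs(cfg, out)
        summary["n_probes"], summary["n_samples"] = map(int, matrix.shape)

        stage_name = "preprocess"
        matrix, design = preprocess.average_technical_replicates(matrix, design)
        means = preprocess.compute_treatment_means(matrix, design)
        means = preprocess.filter_expressed(means, params["expression_floor"],
                                            params["min_treatments"])
        summary["n_probes_expressed"] = int(len(means))
        gene_means = preprocess.map_to_genes(means, probe_map, mode=params["map_mode"])
        summary["n_rows_mapped"] = int(len(gene_means))
        _write_means(gene_means, out / "treatment_means.tsv")

        stage_name = "differential"
        diff = differential.compute_diff(gene_means)
        for s in diff.d.columns:
            differential.pif_table(diff, s).to_csv(out / f"ma_stage{s}.tsv", sep="\t")
        cum = differential.cumulative_de(diff)
        cum.to_csv(out / "cumulative_de.tsv", sep="\t")
        dev = differential.devreg_score(gene_means, breed=params["devreg_breed"])
        dev.to_csv(out / "devreg.tsv", sep="\t")
        summary["ma_counts"] = {
            int(s): int(len(differential.ma_filter(diff, s, params["ma_threshold"])))
            for s in diff.d.columns}
        pif_final = diff.pif[params["skew_stage"]].dropna()
        top, bottom = differential.extreme_slice(
            pif_final.sort_values(ascending=False), params["extreme_fraction"])
        genesets.export_ranked_list(
            pif_final.sort_values(ascending=False).index, out,
            prefix=f"pif_{params['skew_stage']}", top=top, bottom=bottom)

        stage_name = "rif"
        if regulator_list:
            sel = rif_mod.select_de_genes(diff, rule=params["selection"],
                                          fraction=params["rif_fraction"])
            profiles = rif_mod.breed_correlation_profiles(gene_means, regulator_list, sel)
            rif_table = rif_mod.standardize_and_rank(
                rif_mod.compute_rif(profiles, sel), cutoff=params["z_cutoff"])
            rif_table.to_csv(out / "rif.tsv", sep="\t")
            summary["rif"] = {"n_regulators": int(len(rif_table)),
                              "n_de": int(sel.n_de),
                              "n_extreme_both": int(rif_table["extreme_both"].sum())}
        else:
            logger.warning("run_pipeline: no regulator list; rif stage skipped")
            summary["rif"] = None

        stage_name = "genesets"
        if mito_set is not None:
            matched = genesets.match_set(diff.index, mito_set)
            skew = genesets.sign_split(diff, params["skew_stage"], rows=matched)
            pd.DataFrame([asdict(skew)]).to_csv(out / "mito_skew.tsv", sep="\t", index=False)
            summary["mito_skew"] = asdict(skew)
        else:
            summary["mito_skew"] = None

        stage_name = "report"
        zs = row_zscore(gene_means)
        if len(zs) >= 2:
            cl = hcluster(zs, axis="rows", distance=params["cluster_distance"],
                          linkage=params["cluster_linkage"])
            pd.Series(cl.row_order).to_csv(out / "row_order.tsv", sep="\t",
                                           index=False, header=["row_id"])
        for s in diff.d.columns:
            md = ma_plot_data(diff, s, params["ma_threshold"])
            plot_ma(md, s, out / f"ma_stage{s}.png")
        if truth is not None:
            summary["truth_seed"] = truth.seed
    except Exception as exc:  # noqa: BLE001 - re-raise with stage provenance
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return out


_DEFAULT_PARAMS = {
    "expression_floor": preprocess.DEFAULT_EXPRESSION_FLOOR,
    "min_treatments": 7,
    "map_mode": "best-probe",
    "ma_threshold": differential.DEFAULT_MA_THRESHOLD,
    "extreme_fraction": 0.01,
    "selection": rif_mod.DEFAULT_SELECTION_RULE,
    "rif_fraction": rif_mod.DEFAULT_SELECTION_FRACTION,
    "z_cutoff": rif_mod.DEFAULT_Z_CUTOFF,
    "devreg_breed": "BA",
    "skew_stage": 260,
    "cluster_distance": "pearson",
    "cluster_linkage": "average",
}


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text)
    return json.loads(text)


def _load_inputs(cfg: dict, out: Path):
    truth = None
    if "simulate" in cfg:
        sim_cfg = simulate.SimulationConfig(**cfg.get("simulate") or {})
        matrix, design, probe_map, truth = simulate.simulate_dataset(sim_cfg)
        regulator_list = truth.regulators
        mito = truth.mito_gene_names
        mito_set = genesets.GeneSet("mito", mito) if mito else None
        return matrix, design, probe_map, regulator_list, mito_set, truth
    inputs = cfg.get("inputs")
    if not inputs:
        raise ValueError("config needs a 'simulate' or 'inputs' section")
    matrix = mio.read_matrix(inputs["matrix"])
    design = mio.read_design(inputs["design"])
    probe_map = mio.read_probe_map(inputs["probe_map"])
    regulator_list = (mio.read_gene_list(inputs["regulators"])
                      if inputs.get("regulators") else [])
    mito_set = (genesets.GeneSet.from_file(inputs["mito_set"])
                if inputs.get("mito_set") else None)
    return matrix, design, probe_map, regulator_list, mito_set, truth


def _write_means(means: pd.DataFrame, path: Path) -> None:
    out = means.copy()
    out.columns = [f"{b}_{s}" for b, s in out.columns]
    out.to_csv(path, sep="\t")
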