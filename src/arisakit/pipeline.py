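"""End-to-end comparison of the fingerprinting and sequencing method arms.

``run_comparison`` executes the fixed linear workflow

    process fingerprint peaks -> OTU tables -> alpha diversity ->
    Bray-Curtis matrices -> within-group similarity -> similarity
    correlation -> ANOSIM (global + pairwise) -> PCoA -> Procrustes

and returns a :class:`ComparisonReport`; ``render_report`` writes it as a
JSON report, TSV tables and static scatter plots. Reports regenerate
byte-identically from the same config and seed: every stochastic stage is
seeded by a deterministic derivation from the run seed, and no timestamps
enter the report files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arisa, diversity, group_tests, ordination, simulate
from .errors import ConfigError
from .io import (
    DistanceMatrix,
    OTUTable,
    SampleMetadata,
    check_metadata_covers,
    read_metadata,
    read_otu_table,
    read_peak_table,
    remove_rare_otus,
    write_distance_matrix,
    write_otu_table,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Inputs and parameters of one comparison run.

    Exactly one of {real input paths, ``simulate=True``} must be set.
    """

    peaks_path: str | None = None
    pyro_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = False
    community_spec: object | None = None  # CommunitySpec, defaulted in __post_init__
    signal_model: object | None = None  # ArisaSignalModel, defaulted likewise
    filter_params: arisa.FilterParams = field(default_factory=arisa.FilterParams)
    scheme: arisa.BinningScheme = field(default_factory=arisa.BinningScheme)
    replicate_threshold: float = 0.8
    rare_otu_min_count: int = 3
    anosim_permutations: int = 9999
    procrustes_permutations: int = 1000
    mantel_permutations: int = 9999
    n_axes: int = 3
    seed: int = 17

    def __post_init__(self) -> None:
        real = all(p is not None for p in (self.peaks_path, self.pyro_path, self.metadata_path))
        some_real = any(p is not None for p in (self.peaks_path, self.pyro_path, self.metadata_path))
        if self.simulate and some_real:
            raise ConfigError("give either input paths or simulate=True, not both")
        if not self.simulate and not real:
            raise ConfigError("need peaks, pyro table and metadata paths (or simulate=True)")
        if self.community_spec is None:
            self.community_spec = simulate.CommunitySpec()
        if self.signal_model is None:
            self.signal_model = simulate.ArisaSignalModel()


@dataclass
class ComparisonReport:
    """All numbers produced by one run, JSON-serializable."""

    content: dict

    def to_json(self) -> str:
        return json.dumps(self.content, sort_keys=True, indent=2, allow_nan=False)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        content = json.loads(text)
        if content.get("schema_version") != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported report schema {content.get('schema_version')!r}"
            )
        return cls(content)


def _stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, extra)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] & 0x7FFFFFFF)


def _df_records(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.reset_index().to_json(orient="records"))


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Execute the full workflow and return the comparison report."""
    t0 = time.perf_counter()

    # ---- ingest ---------------------------------------------------------
    if config.simulate:
        data = simulate.simulate_dataset(
            spec=config.community_spec,
            model=config.signal_model,
            seed=config.seed,
        )
        peaks, pyro_counts, meta = data["peaks"], data["pyro"], data["metadata"]
    else:
        try:
            peaks = read_peak_table(config.peaks_path)
            pyro_counts = read_otu_table(config.pyro_path)
            meta = read_metadata(config.metadata_path)
        except Exception as exc:
            raise type(exc)(f"stage 'ingest': {exc}") from exc
    _stage("ingest", t0, peaks=len(peaks), pyro_samples=pyro_counts.n_samples)

    # ---- fingerprint processing ----------------------------------------
    t1 = time.perf_counter()
    arisa_table, qc_report = arisa.process_peak_table(
        peaks, config.filter_params, config.scheme, config.replicate_threshold
    )
    check_metadata_covers(arisa_table, meta)
    _stage("process-arisa", t1, samples=arisa_table.n_samples, bins=arisa_table.n_otus)

    # ---- sequencing table ----------------------------------------------
    t1 = time.perf_counter()
    pyro_filtered = remove_rare_otus(pyro_counts, config.rare_otu_min_count)
    check_metadata_covers(pyro_filtered, meta)
    pyro_table = pyro_filtered.to_proportions()
    _stage("pyro-table", t1, otus_in=pyro_counts.n_otus, otus_kept=pyro_filtered.n_otus)

    # common samples (QC failures drop out of the paired analyses)
    common = [s for s in pyro_table.sample_ids if s in arisa_table.sample_ids]
    arisa_common = OTUTable(arisa_table.data.loc[common], arisa_table.abundance_kind)
    pyro_common = OTUTable(pyro_table.data.loc[common], pyro_table.abundance_kind)

    # ---- alpha diversity -------------------------------------------------
    t1 = time.perf_counter()
    tables = {"pyrosequencing": pyro_common, "arisa": arisa_common}
    alpha = {}
    for method, tab in tables.items():
        summary = diversity.alpha_summary(tab, meta)
        obs = diversity.observed_otus(tab)
        h = diversity.shannon(tab)
        alpha[method] = {
            "per_group": _df_records(summary),
            "per_sample": {
                sid: {"observed_otus": int(obs[sid]), "shannon_h": float(h[sid])}
                for sid in tab.sample_ids
            },
            "otu_count_tests": _df_records(
                diversity.pairwise_group_t_tests(obs, meta)),
            "shannon_tests": _df_records(
                diversity.pairwise_group_t_tests(h, meta)),
        }
    _stage("alpha", t1)

    # ---- beta diversity --------------------------------------------------
    t1 = time.perf_counter()
    dms = {m: diversity.distance_matrix(t) for m, t in tables.items()}
    within = {m: _df_records(diversity.within_group_similarity(d, meta))
              for m, d in dms.items()}
    method_cmp = diversity.compare_method_similarity(
        dms["arisa"], dms["pyrosequencing"], meta, "arisa", "pyrosequencing"
    )
    corr = diversity.correlate_similarity_vectors(
        dms["arisa"], dms["pyrosequencing"],
        n_perm=config.mantel_permutations, seed=_sub_seed(config.seed, 1),
    )
    _stage("beta", t1)

    # ---- group tests -----------------------------------------------------
    t1 = time.perf_counter()
    group_order = sorted(set(meta.groups.values()))
    anosim_out = {}
    for k, (method, dm) in enumerate(dms.items()):
        glob = group_tests.anosim(
            dm, meta, n_perm=config.anosim_permutations,
            seed=_sub_seed(config.seed, 10 + k),
        )
        pw = group_tests.pairwise_anosim(
            dm, meta, n_perm=config.anosim_permutations,
            seed=_sub_seed(config.seed, 20 + k),
        )
        matrix = group_tests.anosim_matrix(pw, group_order)
        anosim_out[method] = {
            "global": {"R": glob.R, "p": glob.p,
                       "n_permutations": glob.n_permutations,
                       "exhaustive": glob.exhaustive},
            "pairwise": _df_records(pw),
            "matrix": {"groups": group_order,
                       "values": matrix.to_numpy().tolist()},
        }
    _stage("anosim", t1)

    # ---- ordination ------------------------------------------------------
    t1 = time.perf_counter()
    ords = {m: ordination.pcoa(d, n_axes=config.n_axes) for m, d in dms.items()}
    proc = ordination.procrustes_monte_carlo(
        ords["pyrosequencing"], ords["arisa"], n_axes=config.n_axes,
        n_perm=config.procrustes_permutations, seed=_sub_seed(config.seed, 30),
    )
    pcoa_out = {
        m: {
            "labels": o.labels,
            "coordinates": np.round(o.coordinates, 12).tolist(),
            "eigenvalues": np.round(o.eigenvalues, 12).tolist(),
            "proportion_explained": np.round(o.proportion_explained, 12).tolist(),
            "n_negative_eigenvalues": o.n_negative_eigenvalues,
        }
        for m, o in ords.items()
    }
    _stage("ordination", t1)

    report = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {
            "seed": config.seed,
            "min_rfu": config.filter_params.min_rfu,
            "min_relative_intensity": config.filter_params.min_relative_intensity,
            "replicate_threshold": config.replicate_threshold,
            "rare_otu_min_count": config.rare_otu_min_count,
            "anosim_permutations": config.anosim_permutations,
            "procrustes_permutations": config.procrustes_permutations,
            "mantel_permutations": config.mantel_permutations,
            "n_axes": config.n_axes,
            "simulated": config.simulate,
        },
        "n_samples": len(common),
        "groups": group_order,
        "sample_groups": {s: meta.group_of(s) for s in common},
        "qc": _df_records(qc_report),
        "alpha": alpha,
        "within_group_similarity": within,
        "method_similarity_tests": _df_records(method_cmp),
        "similarity_correlation": {
            "pearson_r": corr.pearson_r,
            "r_squared": corr.r_squared,
            "p_parametric": corr.p_parametric,
            "p_permutation": corr.p_permutation,
            "n_pairs": corr.n_pairs,
        },
        "anosim": anosim_out,
        "pcoa": pcoa_out,
        "procrustes": {
            "m_squared": proc.m_squared,
            "p": proc.p,
            "n_permutations": proc.n_permutations,
            "n_axes": config.n_axes,
        },
    }
    _stage("report", t0)
    rep = ComparisonReport(report)
    rep._distance_matrices = dms  # for render_report; not serialized
    rep._tables = tables
    rep._ordinations = ords
    return rep


def render_report(report: ComparisonReport, out_dir: str | Path) -> list[Path]:
    """Write report.json, TSV tables and scatter plots; return file list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    p = out / "report.json"
    p.write_text(report.to_json() + "\n", encoding="utf-8")
    files.append(p)

    content = report.content
    # alpha summary TSV
    rows = []
    for method, block in content["alpha"].items():
        for rec in block["per_group"]:
            rows.append({"method": method, **rec})
    p = out / "alpha_summary.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    files.append(p)

    # ANOSIM matrices
    for method, block in content["anosim"].items():
        m = pd.DataFrame(block["matrix"]["values"],
                         index=block["matrix"]["groups"],
                         columns=block["matrix"]["groups"])
        m.index.name = method
        p = out / f"anosim_{method}.tsv"
        m.to_csv(p, sep="\t")
        files.append(p)

    dms = getattr(report, "_distance_matrices", None)
    if dms:
        for method, dm in dms.items():
            p = out / f"distance_{method}.tsv"
            write_distance_matrix(dm, p)
            files.append(p)
    tables = getattr(report, "_tables", None)
    if tables:
        for method, tab in tables.items():
            p = out / f"otu_table_{method}.tsv"
            write_otu_table(tab, p)
            files.append(p)

    files.extend(_render_plots(report, out))
    return files


def _render_plots(report: ComparisonReport, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files: list[Path] = []
    ords = getattr(report, "_ordinations", None)
    if not ords:
        return files
    meta_groups = report.content["groups"]
    cmap = plt.get_cmap("tab10")
    colors = {g: cmap(i % 10) for i, g in enumerate(meta_groups)}

    pcoa_block = report.content["pcoa"]
    for method, o in ords.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        X = o.coordinates
        sample_groups = report.content["sample_groups"]
        for g in meta_groups:
            idx = [i for i, s in enumerate(o.labels) if sample_groups.get(s) == g]
            ax.scatter(X[idx, 0], X[idx, 1], s=25, color=colors[g], label=g)
        prop = pcoa_block[method]["proportion_explained"]
        ax.set_xlabel(f"PCo1 ({100 * prop[0]:.1f}%)" if prop else "PCo1")
        ax.set_ylabel(f"PCo2 ({100 * prop[1]:.1f}%)" if len(prop) > 1 else "PCo2")
        ax.set_title(f"PCoA (Bray-Curtis), {method}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / f"pcoa_{method}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        files.append(p)

    # Procrustes superimposition: segments join the two method read-outs
    if len(ords) == 2:
        (m1, o1), (m2, o2) = ords.items()
        A = _center_scale(o1.coordinates[:, :2])
        B = _center_scale(o2.coordinates[:, :2])
        U, s, Vt = np.linalg.svd(A.T @ B)
        B = B @ (Vt.T @ U.T).T * s.sum()
        fig, ax = plt.subplots(figsize=(5, 4))
        for i in range(A.shape[0]):
            ax.plot([A[i, 0], B[i, 0]], [A[i, 1], B[i, 1]],
                    color="0.6", lw=0.8, zorder=1)
        ax.scatter(A[:, 0], A[:, 1], s=22, color="tab:orange", label=m1, zorder=2)
        ax.scatter(B[:, 0], B[:, 1], s=22, color="black", label=m2, zorder=2)
        m2_stat = report.content["procrustes"]["m_squared"]
        ax.set_title(f"Procrustes superimposition (M² = {m2_stat:.3f})")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "procrustes.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        files.append(p)
    return files


def _center_scale(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return Xc / np.linalg.norm(Xc)
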