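"""End-to-end orchestration and the synthetic full-study rerun.

``run_all`` drives the file-based pipeline (count fitting, resolution,
landscape classification, constraint scan, sectoring statistics) from a
flat configuration, writing each stage's TSV atomically plus a manifest of
seeds and input digests. ``study_rerun`` is the self-contained synthetic
driver: it regenerates every input with the study's stated design
(50,000 cells at generations 20/40, 8x8 screens, well-level noise
calibrated to a 0.0017 null SD, three underlying fitness classes) and
recomputes the headline quantities — assay resolution, fitness-class
clustering, neutral-path existence and absorption, exact sectoring tests,
detection limit, estimator calibration, and the null behaviour of the
relaxed-constraint LRT.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2

from . import constraint, io, landscape as land, phylo, presets, simulate, stats
from .fitness import (
    AssayConfig,
    SelectionEstimate,
    detection_limit,
    estimate_resolution,
    fit_well,
    logistic_trajectory,
)

__all__ = [
    "PipelineConfig",
    "fit_screen",
    "s_matrix",
    "estimates_map",
    "run_all",
    "study_rerun",
]


def fit_screen(counts_df: pd.DataFrame, config: AssayConfig | None = None) -> pd.DataFrame:
    """Fit every well of a long count table; returns the estimate schema."""
    meta = counts_df.drop_duplicates("well_id").set_index("well_id")
    rows = []
    for well in io.counts_to_wells(counts_df):
        est = fit_well(well, config)
        rows.append(
            {
                "well_id": well.well_id,
                "green_genotype": meta.loc[well.well_id, "green_genotype"],
                "red_genotype": meta.loc[well.well_id, "red_genotype"],
                "s": est.s,
                "R0_hat": est.R0_hat if est.R0_hat is not None else np.nan,
                "status": est.status,
                "se": est.se if est.se is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=io.ESTIMATE_COLUMNS)


def s_matrix(estimates: pd.DataFrame) -> pd.DataFrame:
    """Genotype x genotype selection-coefficient matrix.

    Entry [red, green] is the fitted s of the red genotype relative to the
    green one; censored wells already carry the +/-0.3 bound and wells not
    performed are NaN.
    """
    reds = sorted(estimates["red_genotype"].unique())
    greens = sorted(estimates["green_genotype"].unique())
    mat = pd.DataFrame(np.nan, index=reds, columns=greens)
    for row in estimates.itertuples():
        mat.loc[row.red_genotype, row.green_genotype] = row.s
    return mat


def estimates_map(
    estimates: pd.DataFrame,
) -> dict[tuple[str, str], list[SelectionEstimate]]:
    """Replicate contrasts keyed by ordered genotype pair.

    The two fluorophore-swapped wells of an unordered pair are merged under
    the lexicographically first-ordered key (first genotype focal); the
    swapped well enters with its sign flipped.
    """
    out: dict[tuple[str, str], list[SelectionEstimate]] = {}
    for row in estimates.itertuples():
        red, green = str(row.red_genotype), str(row.green_genotype)
        if red == green:
            continue
        est = SelectionEstimate(
            str(row.well_id), float(row.s), status=str(row.status),
            se=None if pd.isna(row.se) else float(row.se),
        )
        key = (red, green) if red < green else (green, red)
        if key != (red, green):  # well measures red-vs-green; flip to key order
            est = SelectionEstimate(
                est.well_id, -est.s, status=est.status, se=est.se
            )
        out.setdefault(key, []).append(est)
    return out


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass
class PipelineConfig:
    """Paths, assay constants and seeds for the file-based pipeline.

    Optional stages (landscape, constraint scan, sectoring stats) are
    skipped cleanly when their inputs are absent.
    """

    out_dir: str | Path = "dupfit_out"
    counts: str | Path | None = None
    genotypes: str | Path | None = None
    pre_alignment: str | Path | None = None
    full_alignment: str | Path | None = None
    tree: str | Path | None = None
    sectoring: str | Path | None = None
    sectoring_reference: str = "WT"
    landscape_reference: str | None = None
    landscape_source: str | None = None
    landscape_target: str | None = None
    assay: AssayConfig = field(default_factory=AssayConfig)
    seed: int = 0
    simulate_screen: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = io.read_config(path)
        kwargs: dict = {}
        assay_kwargs: dict = {}
        assay_fields = {f.name for f in dataclasses.fields(AssayConfig)}
        for key, val in raw.items():
            if key in assay_fields:
                assay_kwargs[key] = type(getattr(AssayConfig(), key))(val)
            elif key == "seed":
                kwargs["seed"] = int(val)
            elif key == "simulate_screen":
                kwargs["simulate_screen"] = val.lower() in ("1", "true", "yes")
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = val
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        if assay_kwargs:
            kwargs["assay"] = AssayConfig(**assay_kwargs)
        return cls(**kwargs)


def _atomic_write(write_fn, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary.

    Outputs land in ``config.out_dir``: estimates.tsv, resolution.tsv, and
    when inputs allow landscape.tsv / landscape.dot, constraint_tests.tsv,
    sectoring.tsv, plus manifest.json recording seeds and input digests.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "inputs": {}, "stages": [], "outputs": {}}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = _digest(path)

    # --- counts: read or simulate -------------------------------------
    if config.counts is not None:
        counts = io.read_counts(config.counts)
        manifest["inputs"]["counts"] = _digest(config.counts)
    elif config.simulate_screen:
        genos = presets.reconstructed_genotypes()
        design = simulate.ScreenDesign.all_by_all([g.label for g in genos])
        counts = simulate.simulate_screen(
            design,
            presets.class_assignment(genos),
            simulate.SimCompetitionConfig(
                bio_sd=simulate.calibrated_bio_sd(), seed=config.seed
            ),
        )
        path = out / "counts.tsv"
        _atomic_write(lambda p: io.write_counts(counts, p), path)
        record("counts", path)
    else:
        raise ValueError("no counts given and simulate_screen disabled")
    manifest["stages"].append("counts")

    # --- fitting and resolution ---------------------------------------
    estimates = fit_screen(counts, config.assay)
    path = out / "estimates.tsv"
    _atomic_write(lambda p: io.write_estimates(estimates, p), path)
    record("estimates", path)
    manifest["stages"].append("fit")

    diag = estimates[estimates.green_genotype == estimates.red_genotype]
    if len(diag) >= 2:
        res = estimate_resolution(diag["s"], call_threshold=config.assay.call_threshold)
        res_df = pd.DataFrame(
            [{"mean_s": res.mean_s, "sd_s": res.sd_s, "resolution": res.resolution,
              "call_threshold": res.call_threshold, "n": res.n}]
        )
        path = out / "resolution.tsv"
        _atomic_write(lambda p: res_df.to_csv(p, sep="\t", index=False), path)
        record("resolution", path)
        manifest["stages"].append("resolution")

    # --- landscape -----------------------------------------------------
    if config.genotypes is not None or config.simulate_screen:
        if config.genotypes is not None:
            genos = io.read_genotypes(config.genotypes)
            manifest["inputs"]["genotypes"] = _digest(config.genotypes)
        else:
            genos = presets.reconstructed_genotypes()
        scape = land.build_landscape(genos)
        land.classify_edges(
            scape, estimates_map(estimates), config.assay,
            reference=config.landscape_reference,
        )
        path = out / "landscape.tsv"
        _atomic_write(lambda p: io.write_landscape(scape, p), path)
        record("landscape", path)
        _atomic_write(lambda p: io.write_dot(scape, p), out / "landscape.dot")
        manifest["stages"].append("landscape")

    # --- constraint scan (optional) ------------------------------------
    if config.pre_alignment and config.full_alignment and config.tree:
        model = phylo.PhyloModel(phylo.read_tree(config.tree))
        scan = constraint.scan_protein(
            io.read_fasta(config.pre_alignment),
            io.read_fasta(config.full_alignment),
            model,
            seed=config.seed,
        )
        for key in ("pre_alignment", "full_alignment", "tree"):
            manifest["inputs"][key] = _digest(getattr(config, key))
        path = out / "constraint_tests.tsv"
        _atomic_write(lambda p: scan.to_frame().to_csv(p, sep="\t", index=False), path)
        record("constraint_tests", path)
        manifest["stages"].append("constraint_scan")
    else:
        manifest["stages"].append("constraint_scan:skipped")

    # --- sectoring stats (optional) ------------------------------------
    if config.sectoring is not None:
        df = pd.read_csv(config.sectoring, sep="\t")
        tables = [
            stats.SectoringTable(r.genotype, int(r.sectored), int(r.white))
            for r in df.itertuples()
        ]
        summary = stats.sectoring_summary(tables, config.sectoring_reference)
        manifest["inputs"]["sectoring"] = _digest(config.sectoring)
        path = out / "sectoring.tsv"
        _atomic_write(lambda p: summary.to_csv(p, sep="\t", index=False), path)
        record("sectoring", path)
        manifest["stages"].append("sectoring")
    else:
        manifest["stages"].append("sectoring:skipped")

    _atomic_write(
        lambda p: Path(p).write_text(json.dumps(manifest, indent=2, sort_keys=True)),
        out / "manifest.json",
    )
    return manifest


# ---------------------------------------------------------------------------
# synthetic full-study rerun


def _partition_agreement(labels: pd.Series, truth: Mapping[str, str]) -> float:
    """Best one-to-one matching accuracy between clusters and true classes."""
    truth_names = sorted(set(truth.values()))
    cluster_ids = sorted(labels.unique())
    conf = np.zeros((len(cluster_ids), len(truth_names)))
    for geno, cl in labels.items():
        conf[cluster_ids.index(cl), truth_names.index(truth[geno])] += 1
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(labels)


def null_screen_resolution(seed: int, n_cells: int = 50_000) -> dict:
    """Simulate the 64-well null screen of genetically identical spores and
    summarize the fitted selection coefficients."""
    labels = [f"spore{i}" for i in range(8)]
    design = simulate.ScreenDesign.all_by_all(labels)
    counts = simulate.simulate_screen(
        design,
        {l: 0.0 for l in labels},
        simulate.SimCompetitionConfig(
            n_cells=n_cells, bio_sd=simulate.calibrated_bio_sd(n_cells=n_cells), seed=seed
        ),
    )
    est = fit_screen(counts)
    res = estimate_resolution(est["s"])
    return {
        "n_wells": len(est),
        "mean_s": res.mean_s,
        "sd_s": res.sd_s,
        "resolution": res.resolution,
    }


def class_recovery(seed: int, n_seeds: int = 100) -> dict:
    """Simulate the three-class screen repeatedly; cluster and score
    agreement with the generative class labels."""
    genos = presets.reconstructed_genotypes()
    truth = {g.label: presets.true_fitness_class(g) for g in genos}
    assignment = presets.class_assignment(genos)
    design = simulate.ScreenDesign.all_by_all(list(truth))
    rng = np.random.default_rng(seed)
    agreements, n_classes = [], []
    for sub in rng.integers(0, 2**31 - 1, size=n_seeds):
        counts = simulate.simulate_screen(
            design,
            assignment,
            simulate.SimCompetitionConfig(
                bio_sd=simulate.calibrated_bio_sd(), seed=int(sub)
            ),
        )
        mat = s_matrix(fit_screen(counts))
        result = land.cluster_fitness_classes(mat, wildtype=presets.EXTANT_LABEL)
        n_classes.append(result.n_classes)
        agreements.append(_partition_agreement(result.labels, truth))
    return {
        "n_seeds": n_seeds,
        "mean_agreement": float(np.mean(agreements)),
        "fraction_three_classes": float(np.mean([k == 3 for k in n_classes])),
        "modal_n_classes": int(pd.Series(n_classes).mode().iloc[0]),
    }


def landscape_paths(seed: int) -> dict:
    """Classify the reconstructed landscape from one simulated screen and
    enumerate neutral paths from the single-copy ancestor to the extant
    pair."""
    genos = presets.reconstructed_genotypes()
    design = simulate.ScreenDesign.all_by_all([g.label for g in genos])
    counts = simulate.simulate_screen(
        design,
        presets.class_assignment(genos),
        simulate.SimCompetitionConfig(bio_sd=simulate.calibrated_bio_sd(), seed=seed),
    )
    est = fit_screen(counts)
    scape = land.build_landscape(genos)
    land.classify_edges(scape, estimates_map(est), reference=presets.EXTANT_LABEL)
    paths = land.find_neutral_paths(scape, presets.SOURCE_LABEL, presets.EXTANT_LABEL)
    determinate = [p for p in paths if not p.indeterminate]
    return {
        "n_neutral_paths": len(determinate),
        "max_degenerations": max((p.degenerations for p in determinate), default=0),
        "extant_absorbing": land.is_absorbing(scape, presets.EXTANT_LABEL),
    }


def estimator_calibration(
    seed: int,
    true_s: Sequence[float] = (-0.05, -0.013, 0.0, 0.01),
    n_wells: int = 1000,
    n_cells: int = 50_000,
    timepoints: tuple[float, float] = (20.0, 40.0),
) -> pd.DataFrame:
    """Bias and SD of the two-timepoint estimator over simulated wells
    (no biological noise), against the delta-method SD."""
    rng = np.random.default_rng(seed)
    t1, t2 = timepoints
    rows = []
    for s in true_s:
        p = logistic_trajectory(0.5, s, np.array(timepoints))
        r = rng.binomial(n_cells, p, size=(n_wells, 2))
        g = n_cells - r
        s_hat = (np.log(r[:, 1] / g[:, 1]) - np.log(r[:, 0] / g[:, 0])) / (t2 - t1)
        sd_pred = np.sqrt(np.sum(1.0 / (n_cells * p * (1 - p)))) / (t2 - t1)
        rows.append(
            {
                "true_s": s,
                "mean_s_hat": float(np.mean(s_hat)),
                "bias": float(np.mean(s_hat) - s),
                "sd_emp": float(np.std(s_hat, ddof=1)),
                "sd_delta": float(sd_pred),
                "n_wells": n_wells,
            }
        )
    return pd.DataFrame(rows)


def lrt_null_calibration(
    seed: int,
    n_regions: int = 1000,
    n_columns: int = 30,
    rho: float = 0.3,
) -> dict:
    """Type-I error of the relaxed-constraint LRT under the null.

    Regions evolve with a single shared rate ``rho`` on an 8-taxon tree
    with a flagged post-duplication clade; the test should reject at ~5%
    against the chi-square(1) 0.05 threshold.
    """
    newick = (
        "((pre1:0.3,pre2:0.3):0.2,((a1:0.2,a2:0.2):0.2,"
        "((b1:0.15,b2:0.15):0.1,(b3:0.15,b4:0.15):0.1)DUP:0.2):0.2);"
    )
    rng = np.random.default_rng(seed)
    rejections = 0
    lrts = []
    for sub in rng.integers(0, 2**31 - 1, size=n_regions):
        cfg = simulate.SimAlignmentConfig(
            tree=newick,
            length=n_columns,
            regions=((0, n_columns, rho),),
            seed=int(sub),
        )
        aln = simulate.simulate_alignment(cfg)
        model = cfg.model()
        region = constraint.MappedRegion(
            constraint.ConstraintRegion(0, n_columns, 1.0), 0, n_columns
        )
        test = constraint.lrt_constraint_change(region, aln, model, "DUP")
        lrts.append(test.lrt)
        if test.p < 0.05:
            rejections += 1
    return {
        "n_regions": n_regions,
        "rejection_rate": rejections / n_regions,
        "median_lrt": float(np.median(lrts)),
        "chi2_threshold": float(chi2.ppf(0.95, 1)),
    }


def study_rerun(
    seed: int = 0,
    n_cluster_seeds: int = 100,
    n_calibration_wells: int = 1000,
    n_lrt_regions: int = 1000,
) -> dict:
    """Regenerate every synthetic input and recompute the headline numbers.

    Returns a nested report: assay resolution from a null screen, fitness
    class recovery, neutral-path/absorption analysis of the reconstructed
    landscape, the exact sectoring tests on the reference colony-count tables,
    the detection limit implied by the counting rule, estimator
    calibration, null LRT behaviour, and the dilution/population-size
    arithmetic.
    """
    from .fitness import estimate_ne

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)]

    report: dict = {}
    report["resolution"] = null_screen_resolution(seeds[0])
    report["clustering"] = class_recovery(seeds[1], n_seeds=n_cluster_seeds)
    report["landscape"] = landscape_paths(seeds[2])
    report["sectoring"] = {
        "bub1_delta_p": stats.fisher_exact_2x2(29, 65, 3, 131),
        "mad3_delta_p": stats.fisher_exact_2x2(5, 177, 3, 131),
        "scp_rescue_p": stats.fisher_exact_2x2(3, 207, 3, 131),
    }
    report["detection_limit_s"] = detection_limit(AssayConfig(), R0=0.5, t_final=40.0)
    report["calibration"] = estimator_calibration(
        seeds[3], n_wells=n_calibration_wells
    ).to_dict("records")
    report["lrt_null"] = lrt_null_calibration(seeds[4], n_regions=n_lrt_regions)
    report["design"] = {
        "screen_wells": len(simulate.ScreenDesign.all_by_all(
            [f"g{i}" for i in range(8)]
        ).wells),
        "doublings_per_day": float(np.log2(1024)),
        "ne_estimate": estimate_ne(),
    }
    return report
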