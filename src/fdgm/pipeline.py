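"""End-to-end orchestration: landmarks -> scores -> discrimination -> accuracy.

One run compares the two analysis branches on the same aligned data:

* GM branch: classical PCA of the flattened Procrustes coordinates;
* functional branch: the landmark curves' multivariate FPCA.

For each requested view-set (single views and/or "combined") the
pipeline averages digitisation replicates, runs GPA once, computes both
score sets, fits score-based LDA (first K scores), and runs the
replicated stratified-split classification protocol on the same splits
for both branches.  "Combined" means the views' x/y curve elements
enter one multivariate FPCA (functional branch) and the views'
Procrustes coordinate blocks are column-concatenated before PCA (GM
branch); both branches consume the identical per-view alignments.

All randomness derives from the master seed, and outputs are written
with fixed numeric formatting, so identical configurations reproduce
byte-identical artefacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import ClassifierSpec, ClassificationReport, default_specs, evaluate_protocol
from .decomposition import MFPCAResult, PCAResult, classical_pca, mfpca
from .discriminant import DiscriminantResult, lda_fit
from .functional import FunctionalDataset, SmoothingSpec, combine_views, to_functional
from .landmark_io import LandmarkDataset, ValidationError, average_replicates, read_manifest
from .procrustes import AlignedDataset, gpa
from .synthetic import SimulationSpec, simulate_dataset

COMBINED = "combined"


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``manifest`` (path to a dataset manifest CSV) or
    ``simulation`` (mapping view name -> SimulationSpec) supplies the
    landmark data.
    """

    manifest: str | Path | None = None
    simulation: dict[str, SimulationSpec] | None = None
    view_sets: list[str] = field(default_factory=lambda: [COMBINED])
    pve_threshold: float = 0.99
    k: int = 3
    reps: int = 20
    train_fraction: float = 0.7
    seed: int = 0
    classifiers: list[ClassifierSpec] = field(default_factory=default_specs)
    smoothing: SmoothingSpec | None = None
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.simulation is None):
            raise ValidationError("provide exactly one of manifest or simulation")
        if self.k < 1:
            raise ValidationError("K must be at least 1")


@dataclass
class BranchResult:
    """One branch (GM or functional) of one view-set."""

    method: str  # "GM" or "FDGM"
    decomposition: PCAResult | MFPCAResult
    scores: np.ndarray  # first K score columns
    lda: DiscriminantResult
    report: ClassificationReport

    @property
    def n_components(self) -> int:
        return self.decomposition.n_components

    @property
    def pve2(self) -> float:
        pve = self.decomposition.pve
        return float(pve[min(1, pve.size - 1)])


@dataclass
class PipelineResult:
    config: RunConfig
    aligned: dict[str, AlignedDataset]
    branches: dict[str, dict[str, BranchResult]]  # view_set -> method -> result
    labels: list[str]
    specimen_ids: list[str]
    log: list[str] = field(default_factory=list)

    def accuracy_table(self) -> pd.DataFrame:
        """Mean (sd) accuracy per classifier x (method, view-set)."""
        rows = []
        for view_set, methods in self.branches.items():
            for method, branch in methods.items():
                for name in branch.report.classifier_names:
                    rows.append(
                        {
                            "view_set": view_set,
                            "method": method,
                            "classifier": name,
                            "mean_accuracy": branch.report.mean_accuracy(name),
                            "sd_accuracy": branch.report.sd_accuracy(name),
                        }
                    )
        return pd.DataFrame(rows)


def _load_views(config: RunConfig) -> dict[str, list[LandmarkDataset]]:
    if config.manifest is not None:
        return read_manifest(config.manifest)
    views = {}
    for view, spec in config.simulation.items():
        replicates, _ = simulate_dataset(spec)
        views[view] = replicates
    return views


def _match_order(reference_ids: list[str], aligned: AlignedDataset) -> AlignedDataset:
    if aligned.specimen_ids == reference_ids:
        return aligned
    index = {s: i for i, s in enumerate(aligned.specimen_ids)}
    missing = set(reference_ids).symmetric_difference(index)
    if missing:
        raise ValidationError(f"specimen ids differ across views: {sorted(missing)}")
    order = [index[s] for s in reference_ids]
    return AlignedDataset(
        coords=aligned.coords[order],
        centroid_sizes=aligned.centroid_sizes[order],
        consensus=aligned.consensus,
        iterations_used=aligned.iterations_used,
        converged=aligned.converged,
        specimen_ids=list(reference_ids),
        labels=[aligned.labels[i] for i in order],
        view=aligned.view,
        objective_history=aligned.objective_history,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full comparison described by ``config``."""
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(f"{time.strftime('%H:%M:%S')} {msg}")

    stage(f"run start (seed={config.seed})")
    views = _load_views(config)
    view_names = list(views.keys())

    averaged = {v: average_replicates(reps) for v, reps in views.items()}
    stage(f"averaged replicates for views: {view_names}")
    aligned = {v: gpa(ds) for v, ds in averaged.items()}
    for v, a in aligned.items():
        stage(f"GPA[{v}]: {a.iterations_used} iterations, converged={a.converged}")

    reference_ids = aligned[view_names[0]].specimen_ids
    aligned = {v: _match_order(reference_ids, a) for v, a in aligned.items()}
    labels = aligned[view_names[0]].labels

    functional = {
        v: to_functional(a, smoothing=config.smoothing) for v, a in aligned.items()
    }

    branches: dict[str, dict[str, BranchResult]] = {}
    for view_set in config.view_sets:
        if view_set == COMBINED:
            if len(view_names) < 2:
                raise ValidationError("'combined' needs at least two views")
            gm_input = np.hstack([aligned[v].flattened() for v in view_names])
            fd: FunctionalDataset = combine_views([functional[v] for v in view_names])
        elif view_set in aligned:
            gm_input = aligned[view_set].flattened()
            fd = functional[view_set]
        else:
            raise ValidationError(
                f"unknown view set {view_set!r}; available: {view_names + [COMBINED]}"
            )

        gm_pca = classical_pca(gm_input)
        fdgm = mfpca(fd, pve_threshold=config.pve_threshold)
        stage(
            f"{view_set}: GM {gm_pca.n_components} PCs, "
            f"functional {fdgm.n_components} MFPCs"
        )

        branches[view_set] = {}
        for method, decomposition in (("GM", gm_pca), ("FDGM", fdgm)):
            k = min(config.k, decomposition.n_components)
            if k < config.k:
                stage(
                    f"{view_set}/{method}: only {k} components available "
                    f"(requested K={config.k})"
                )
            scores = decomposition.scores[:, :k]
            lda = lda_fit(scores, labels)
            report = evaluate_protocol(
                scores,
                labels,
                specs=config.classifiers,
                reps=config.reps,
                train_fraction=config.train_fraction,
                seed0=config.seed,
            )
            branches[view_set][method] = BranchResult(
                method=method,
                decomposition=decomposition,
                scores=scores,
                lda=lda,
                report=report,
            )
            stage(
                f"{view_set}/{method}: LDA separation "
                f"{np.round(lda.separation_percentages, 2).tolist()}%"
            )

    result = PipelineResult(
        config=config,
        aligned=aligned,
        branches=branches,
        labels=list(labels),
        specimen_ids=list(reference_ids),
        log=log,
    )
    if config.outdir is not None:
        write_outputs(result, Path(config.outdir))
    return result


# ---------------------------------------------------------------------------
# Artefact writing

_FLOAT_FMT = "%.12g"


def _scores_frame(result: PipelineResult, branch: BranchResult) -> pd.DataFrame:
    frame = pd.DataFrame(
        branch.scores,
        columns=[f"PC{j + 1}" for j in range(branch.scores.shape[1])],
    )
    frame.insert(0, "specimen_id", result.specimen_ids)
    frame.insert(1, "label", result.labels)
    return frame


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    """Write score tables, eigenvalue tables, LDA outputs and the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for view_set, methods in result.branches.items():
        for method, branch in methods.items():
            prefix = f"{view_set}_{method}".lower()
            _scores_frame(result, branch).to_csv(
                outdir / f"{prefix}_scores.csv", index=False, float_format=_FLOAT_FMT
            )
            eig = branch.decomposition.eigenvalues
            pd.DataFrame(
                {
                    "component": np.arange(1, eig.size + 1),
                    "eigenvalue": eig,
                    "cumulative_pve": branch.decomposition.pve,
                }
            ).to_csv(
                outdir / f"{prefix}_eigenvalues.csv", index=False, float_format=_FLOAT_FMT
            )
            lda_frame = pd.DataFrame(
                branch.lda.projected,
                columns=[f"LD{j + 1}" for j in range(branch.lda.n_axes)],
            )
            lda_frame.insert(0, "specimen_id", result.specimen_ids)
            lda_frame.insert(1, "label", result.labels)
            lda_frame.to_csv(
                outdir / f"{prefix}_lda.csv", index=False, float_format=_FLOAT_FMT
            )

    result.accuracy_table().to_csv(
        outdir / "classification_report.csv", index=False, float_format=_FLOAT_FMT
    )
    report_json = {
        view_set: {
            method: {
                "n_components": branch.n_components,
                "pve_first2": branch.pve2,
                "separation_percentages": branch.lda.separation_percentages.tolist(),
                "classifiers": branch.report.summary(),
            }
            for method, branch in methods.items()
        }
        for view_set, methods in result.branches.items()
    }
    (outdir / "report.json").write_text(json.dumps(report_json, indent=2, sort_keys=True))
    manifest = {
        "package_version": __version__,
        "seed": result.config.seed,
        "k": result.config.k,
        "reps": result.config.reps,
        "train_fraction": result.config.train_fraction,
        "pve_threshold": result.config.pve_threshold,
        "view_sets": result.config.view_sets,
        "n_specimens": len(result.specimen_ids),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")
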