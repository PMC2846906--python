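"""End-to-end pipeline: t-filter -> moment transform -> kernel PLS.

``MomentKPLSPipeline`` bundles the three stages behind a fit/predict
interface over :class:`~momentpls.io.RefinedMatrix` objects so the
validation schemes in :mod:`momentpls.evaluate` can refit everything —
including the t-filter and any width/component selection — inside each
training fold.  Test samples never influence filtering or selection
unless ``global_preprocess`` (the leaky whole-dataset protocol some
historical studies used) is explicitly requested via
:func:`make_pipeline_factory`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import evaluate, kpls, moments, preprocess
from .errors import UsageError
from .io import RefinedMatrix, write_matrix, write_report
from .moments import MOMENT_NAMES

__all__ = ["PipelineConfig", "MomentKPLSPipeline", "make_pipeline_factory", "run_all"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    ``width`` and ``components`` accept "auto" to enable data-driven
    selection (width over ``width_candidates`` by internal CV accuracy;
    components over ``component_candidates`` by inner stratified CV).
    ``alpha`` is the t-filter significance level; ``degree``/``offset``
    parameterise the polynomial kernel.
    """

    alpha: float = 0.01
    width: int | str = 40
    width_candidates: tuple[int, ...] = (20, 30, 40, 50, 60)
    moments: tuple[str, ...] = MOMENT_NAMES
    degree: int = 3
    offset: float = 1.0
    components: int | str = "auto"
    component_candidates: tuple[int, ...] = tuple(range(1, 11))
    t_filter_enabled: bool = True
    equal_var: bool = True
    seed: int = 0

    def kernel_params(self) -> kpls.KernelParams:
        return kpls.KernelParams(degree=self.degree, offset=self.offset)


class MomentKPLSPipeline:
    """Filter + transform + classify, refit from scratch on each fit().

    When ``fixed_filter_indices`` is supplied the t-filter is skipped and
    those row indices are used instead (global-preprocessing mode).
    """

    def __init__(
        self,
        config: PipelineConfig,
        fixed_filter_indices: np.ndarray | None = None,
        fixed_width: int | None = None,
    ):
        self.config = config
        self.fixed_filter_indices = fixed_filter_indices
        self.fixed_width = fixed_width
        self.filter_result_: preprocess.FilterResult | None = None
        self.width_: int | None = None
        self.width_table_: dict | None = None
        self.n_components_: int | None = None
        self.model_: kpls.KPLSModel | None = None

    # -- internal -----------------------------------------------------------
    def _filter_rows(self, matrix: RefinedMatrix) -> RefinedMatrix:
        cfg = self.config
        if self.fixed_filter_indices is not None:
            idx = self.fixed_filter_indices
            self.filter_result_ = None
            return RefinedMatrix(
                matrix.mz_axis[idx], matrix.intensities[idx],
                list(matrix.sample_ids), matrix.labels,
            )
        if not cfg.t_filter_enabled:
            self.filter_result_ = None
            return matrix
        filtered, result = preprocess.t_filter(
            matrix, cfg.alpha, equal_var=cfg.equal_var
        )
        self.filter_result_ = result
        if filtered.n_mz == 0:
            raise UsageError(
                "t-filter removed every m/z row; lower alpha or disable the filter"
            )
        return filtered

    def _choose_width(self, filtered: RefinedMatrix) -> int:
        cfg = self.config
        if self.fixed_width is not None:
            return self.fixed_width
        if cfg.width != "auto":
            return int(cfg.width)
        width, table = moments.select_width(
            filtered,
            cfg.width_candidates,
            self._width_evaluator(),
            cfg.moments,
        )
        self.width_table_ = table
        return width

    def _width_evaluator(self) -> Callable:
        """Internal 5-fold KPLS accuracy on candidate features."""
        cfg = self.config

        def evaluate_fn(feats: moments.MomentFeatures) -> tuple[float, float]:
            from sklearn.model_selection import StratifiedKFold

            y = feats.labels
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=cfg.seed)
            y_true, y_pred = [], []
            for tr, te in skf.split(feats.features.T, y):
                n_comp = min(3, len(tr) - 1)
                model = kpls.fit(
                    feats.features[:, tr], y[tr], cfg.kernel_params(), n_comp
                )
                _, pred = kpls.predict(model, feats.features[:, te])
                y_true.append(y[te])
                y_pred.append(pred)
            ms = evaluate.metrics(
                evaluate.confusion(np.concatenate(y_true), np.concatenate(y_pred))
            )
            return ms.Ac, ms.CC

        return evaluate_fn

    # -- public -------------------------------------------------------------
    def fit(self, matrix: RefinedMatrix) -> "MomentKPLSPipeline":
        cfg = self.config
        filtered = self._filter_rows(matrix)
        self.width_ = self._choose_width(filtered)
        feats = moments.transform(filtered, self.width_, cfg.moments)
        if cfg.components == "auto":
            n_train = feats.features.shape[1]
            candidates = [c for c in cfg.component_candidates if c <= n_train - 1]
            self.n_components_ = kpls.select_components(
                feats.features, feats.labels, candidates, cfg.seed,
                cfg.kernel_params(),
            )
        else:
            self.n_components_ = int(cfg.components)
        self.model_ = kpls.fit(
            feats.features, feats.labels, cfg.kernel_params(), self.n_components_
        )
        self._train_mz = filtered.mz_axis
        self._kept_rows = (
            self.fixed_filter_indices
            if self.fixed_filter_indices is not None
            else (self.filter_result_.kept_indices
                  if self.filter_result_ is not None else None)
        )
        return self

    def _apply_train_rows(self, matrix: RefinedMatrix) -> RefinedMatrix:
        if self._kept_rows is None:
            return matrix
        idx = self._kept_rows
        if idx.size and idx.max() >= matrix.n_mz:
            raise UsageError(
                "test matrix m/z axis does not match the training axis; "
                "align and refine train and test together first"
            )
        return RefinedMatrix(
            matrix.mz_axis[idx], matrix.intensities[idx],
            list(matrix.sample_ids), matrix.labels,
        )

    def predict(self, matrix: RefinedMatrix) -> np.ndarray:
        scores, labels = self.decision_scores(matrix)
        return labels

    def decision_scores(self, matrix: RefinedMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Regression scores and +/-1 labels for new samples.

        The test matrix must live on the same m/z axis as the training
        matrix; the training fold's filter rows and window plan are applied
        unchanged (no refitting on test data).
        """
        if self.model_ is None:
            raise UsageError("pipeline is not fitted")
        test = self._apply_train_rows(matrix)
        if test.n_mz != self._train_mz.size or not np.array_equal(
            test.mz_axis, self._train_mz
        ):
            raise UsageError(
                "test matrix m/z axis does not match the training axis; "
                "align and refine train and test together first"
            )
        feats = moments.transform(test, self.width_, self.config.moments)
        return kpls.predict(self.model_, feats.features)


def make_pipeline_factory(
    config: PipelineConfig,
    matrix: RefinedMatrix | None = None,
    global_preprocess: bool = False,
) -> Callable[[], MomentKPLSPipeline]:
    """Factory for fresh pipelines, as the validation schemes require.

    With ``global_preprocess=True`` the t-filter (and width selection, if
    "auto") run once on the *full* matrix and are frozen into every
    pipeline the factory creates.  This reproduces the historical protocol
    of filtering before cross-validation; it leaks test information and is
    off by default.
    """
    if not global_preprocess:
        return lambda: MomentKPLSPipeline(config)
    if matrix is None:
        raise UsageError("global_preprocess requires the full matrix up front")
    probe = MomentKPLSPipeline(config)
    filtered = probe._filter_rows(matrix)
    width = probe._choose_width(filtered)
    kept = (probe.filter_result_.kept_indices
            if probe.filter_result_ is not None else None)
    return lambda: MomentKPLSPipeline(
        config, fixed_filter_indices=kept, fixed_width=width
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: PipelineConfig,
    sset,
    out_dir: str | Path,
    schemes: Sequence[str] = ("fivefold",),
    repeats: int = 10,
    global_preprocess: bool = False,
) -> dict:
    """Execute preprocess -> transform -> validate and write all artifacts.

    ``sset`` is a :class:`SpectrumSet` (refined here) or an already
    complete :class:`RefinedMatrix`.  Writes the refined matrix, p-values,
    features, one report per scheme, and a manifest recording the config,
    stage-by-stage dimensions and SHA-256 checksums of every output file.
    Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_dims: dict[str, int] = {}

    if isinstance(sset, RefinedMatrix):
        refined = sset
        stage_dims["raw_mz"] = refined.n_mz
    else:
        stage_dims["raw_mz"] = sset.n_mz
        refined = preprocess.refine(sset)
    stage_dims["refined_mz"] = refined.n_mz

    if config.t_filter_enabled:
        filtered, fres = preprocess.t_filter(
            refined, config.alpha, equal_var=config.equal_var
        )
        pvals_path = out_dir / "pvalues.tsv"
        np.savetxt(
            pvals_path,
            np.column_stack([refined.mz_axis, fres.p_values]),
            delimiter="\t", header="mz\tp_value", comments="",
        )
    else:
        filtered, fres = refined, None
        pvals_path = None
    stage_dims["filtered_mz"] = filtered.n_mz

    refined_path = out_dir / "refined.tsv"
    write_matrix(refined, refined_path)

    width = config.width
    if width == "auto":
        probe = MomentKPLSPipeline(config)
        width, _ = moments.select_width(
            filtered, config.width_candidates,
            probe._width_evaluator(), config.moments,
        )
    feats = moments.transform(filtered, int(width), config.moments)
    stage_dims["features"] = feats.n_features
    features_path = out_dir / "features.tsv"
    write_matrix(feats, features_path)

    factory = make_pipeline_factory(
        config, matrix=refined, global_preprocess=global_preprocess
    )
    report_paths = []
    for scheme in schemes:
        if scheme == "fivefold":
            report = evaluate.five_fold_cv(
                factory, refined, repeats=repeats, seed=config.seed
            )
        elif scheme == "proportional":
            report = evaluate.proportional_validation(
                factory, refined, repeats=repeats, seed=config.seed
            )
        elif scheme == "loocv":
            ms, _table = evaluate.loocv(factory, refined)
            report = evaluate.ValidationReport.from_repeats("loocv", [ms], None)
        else:
            raise UsageError(f"unknown validation scheme {scheme!r}")
        rpath = out_dir / f"report_{scheme}.json"
        write_report(report, rpath)
        report_paths.append(rpath)

    outputs = [refined_path, features_path, *report_paths]
    if pvals_path is not None:
        outputs.insert(1, pvals_path)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "width_used": int(width),
        "global_preprocess": global_preprocess,
        "stage_dimensions": stage_dims,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
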