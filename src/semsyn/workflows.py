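"""End-to-end cohort analysis on a synthetic dataset.

Glue that runs the full pipeline the way a study would: build the three
feature streams, derive embedding matrices for every model (lexical lookup
for the restricted spaces, bounded-context extraction through the toy
causal provider for the context-k models), convolve them into per-run
design matrices on top of the confound baseline, fit nested-CV ridge
encoders for every subject, and aggregate ΔR maps into smoothed,
FDR-thresholded group statistics.

Subjects share the stimulus, hence the design matrices; their BOLD runs are
stacked voxel-wise so one nested-CV pass per model scores every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import FeatureStream
from .embeddings import (EmbeddingMatrix, ToyContextualProvider,
                         fixed_context_extract, lookup_embeddings)
from .encoding import (BoldRun, DesignMatrix, EncodingResult, HrfSpec,
                       RidgeConfig, WordEventSeries, delta_r, fit_encoder,
                       make_baseline, make_design, preprocess_bold)
from .group import GroupResult, group_analysis
from .simulate import SimDataset

__all__ = ["CohortResults", "encode_cohort", "unigram_log_frequencies",
           "DEFAULT_MODELS"]

#: model name -> the feature spaces whose design columns are concatenated
DEFAULT_MODELS = {
    "semantic": ("sem",),
    "syntactic": ("syn",),
    "concat": ("sem", "syn"),
    "duplicate": ("sem", "sem"),
    "integral": ("int",),
    "ctx5": ("ctx5",),
    "ctx15": ("ctx15",),
    "ctx45": ("ctx45",),
}


@dataclass
class CohortResults:
    """Per-model encoding results, per-subject ΔR maps and group statistics."""

    subjects: list
    grid: object
    baseline: EncodingResult
    results: dict = field(default_factory=dict)   # model -> EncodingResult (stacked)
    delta: dict = field(default_factory=dict)     # model -> (subjects, voxels) ΔR
    group: dict = field(default_factory=dict)     # model -> GroupResult

    def subject_result(self, model: str, s_idx: int, n_vox: int) -> EncodingResult:
        """Slice one subject's scores out of a stacked result."""
        res = self.results[model] if model != "baseline" else self.baseline
        sl = slice(s_idx * n_vox, (s_idx + 1) * n_vox)
        return EncodingResult(r_cv=res.r_cv[sl], per_fold=res.per_fold[:, sl],
                              alphas=res.alphas[:, sl],
                              label=f"{res.label}/{self.subjects[s_idx]}")


def unigram_log_frequencies(stream: FeatureStream) -> dict:
    """Natural log of relative unigram frequency per symbol of a stream."""
    symbols, counts = np.unique(np.asarray(stream.symbols), return_counts=True)
    rel = counts / counts.sum()
    return dict(zip(symbols.tolist(), np.log(rel)))


def _context_embeddings(ds: SimDataset, k: int) -> EmbeddingMatrix:
    """Bounded-context embeddings over the integral stream, reset per run."""
    windows = sorted(ds.cfg.ctx_decays)
    block = ds.cfg.d_ctx // len(windows)
    decay = np.concatenate([np.full(block, ds.cfg.ctx_decays[kk])
                            for kk in windows])
    provider = ToyContextualProvider(ds.factors.ctx_table, decay)
    stream = ds.factors.streams["integral"]
    run_ids = np.array([t.run_id for t in ds.tokens])
    X = np.empty((len(ds.tokens), provider.d))
    for run in np.unique(run_ids):
        pos = np.flatnonzero(run_ids == run)
        sub = FeatureStream(mode="integral",
                            symbols=[stream.symbols[i] for i in pos],
                            alignment=list(range(len(pos))))
        X[pos] = fixed_context_extract(provider, sub, k).X
    return EmbeddingMatrix(X=X, provenance={"provider": "toy", "mode": "fixed-context",
                                            "k": k})


def _space_embeddings(ds: SimDataset) -> dict:
    """Embedding matrix + stream alignment for every feature space."""
    f = ds.factors
    spaces = {
        "sem": (lookup_embeddings(f.streams["semantic"], f.sem_table),
                f.streams["semantic"].alignment),
        "syn": (lookup_embeddings(f.streams["syntactic"], f.syn_table),
                f.streams["syntactic"].alignment),
        "int": (EmbeddingMatrix(np.hstack([f.sem_tok, f.syn_tok, f.prod_tok]),
                                provenance={"provider": "lookup", "mode": "integral"}),
                f.streams["integral"].alignment),
    }
    for k in (5, 15, 45):
        spaces[f"ctx{k}"] = (_context_embeddings(ds, k),
                             f.streams["integral"].alignment)
    return spaces


def _space_design_columns(ds: SimDataset, spaces: dict, spec: HrfSpec) -> dict:
    """Per-space, per-run HRF-convolved design columns."""
    run_ids = np.array([t.run_id for t in ds.tokens])
    offsets = np.array([t.offset for t in ds.tokens])
    runs = sorted(np.unique(run_ids))
    cols: dict = {}
    for name, (emb, alignment) in spaces.items():
        align = np.asarray(alignment)
        tok_runs = run_ids[align]
        per_run = []
        for ri, run in enumerate(runs):
            sel = tok_runs == run
            ev = WordEventSeries(times=offsets[align[sel]],
                                 amplitudes=emb.X[sel], run_id=int(run))
            per_run.append(make_design(ev, spec, ds.scan_times[ri], tr=ds.cfg.tr))
        cols[name] = per_run
    return cols


def _baseline_designs(ds: SimDataset, spec: HrfSpec) -> list[DesignMatrix]:
    run_ids = np.array([t.run_id for t in ds.tokens])
    offsets = np.array([t.offset for t in ds.tokens])
    int_stream = ds.factors.streams["integral"]
    logf = unigram_log_frequencies(int_stream)
    log_freq_tok = np.array([logf[s] for s in int_stream.symbols])
    designs = []
    for ri, run in enumerate(sorted(np.unique(run_ids))):
        sel = run_ids == run
        ev = WordEventSeries(times=offsets[sel], amplitudes=np.ones(sel.sum()),
                             run_id=int(run))
        designs.append(make_baseline(ev, ds.audio_rms[ri], log_freq_tok[sel],
                                     spec, ds.scan_times[ri], tr=ds.cfg.tr))
    return designs


def encode_cohort(ds: SimDataset, models: dict | None = None,
                  ridge: RidgeConfig | None = None, *, q: float = 0.005,
                  fwhm_mm: float = 6.0, run_group_stats: bool = True,
                  ) -> CohortResults:
    """Fit every encoding model on every subject and aggregate group maps.

    Parameters
    ----------
    ds : SimDataset
        Synthetic study (stimulus, factors, BOLD).
    models : mapping, optional
        Model name -> tuple of feature-space names (columns concatenated on
        top of the baseline).  Defaults to :data:`DEFAULT_MODELS`.
    """
    if models is None:
        models = DEFAULT_MODELS
    if ridge is None:
        ridge = RidgeConfig()
    spec = HrfSpec()
    needed = sorted({s for parts in models.values() for s in parts})
    spaces = {k: v for k, v in _space_embeddings(ds).items() if k in needed}
    space_cols = _space_design_columns(ds, spaces, spec)
    base = _baseline_designs(ds, spec)
    n_runs = len(base)

    subjects = sorted(ds.bold)
    n_vox = ds.grid.n_voxels
    Ys = []
    for ri in range(n_runs):
        Ys.append(np.hstack([preprocess_bold(ds.bold[s][ri]).data
                             for s in subjects]))

    base_X = [b.matrix for b in base]
    res_base = fit_encoder(base_X, Ys, ridge, label="baseline")

    out = CohortResults(subjects=subjects, grid=ds.grid, baseline=res_base)
    n_sub = len(subjects)
    for name, parts in models.items():
        designs = [np.hstack([base_X[ri]] + [space_cols[p][ri] for p in parts])
                   for ri in range(n_runs)]
        res = fit_encoder(designs, Ys, ridge, label=name)
        out.results[name] = res
        dr = delta_r(res, res_base)
        out.delta[name] = dr.reshape(n_sub, n_vox)
        if run_group_stats:
            out.group[name] = group_analysis(
                out.delta[name], ds.grid, q=q, fwhm_mm=fwhm_mm,
                voxel_size_mm=ds.cfg.voxel_size_mm)
    return out
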