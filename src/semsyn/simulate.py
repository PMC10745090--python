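"""Synthetic cohort generator with planted ground truth.

Everything the pipeline consumes is generated here: a multi-run annotated
word stream from a small template grammar (with well-formed constituency
trees and word timings), latent semantic and syntactic factor spaces, and
multi-subject BOLD series in which voxel classes are planted by
construction:

* ``semantic`` — driven by a projection of the content word's identity vector;
* ``syntactic`` — driven by a projection of the (POS, Morph, NCN) triplet vector;
* ``mixed`` — additive combination of a semantic and a syntactic component,
  each at the dedicated-voxel strength;
* ``interaction`` — driven by elementwise *products* of semantic and
  syntactic factors, i.e. signal that no concatenation of the two linear
  spaces can represent;
* ``context5`` / ``context15`` — driven by exponentially decaying averages
  of per-token vectors over a hard window of 5 / 15 tokens, so only
  embedders whose context bound covers the window can capture them fully;
* ``null`` — autocorrelated noise only.

Voxels live on a regular 4 mm lattice split into a planted compartment and
a null compartment separated by two absent lattice layers (the voxel mask
is a subset of the bounding box, as a real brain mask is); hemisphere
labels follow the sign of the x coordinate.  Classes with hemisphere
preferences produce, by design, an overlapping semantic/syntactic peak
geometry on the right (the ``mixed`` block) and a segregated one on the
left (disjoint ``semantic`` and ``syntactic`` blocks).

All randomness flows from one seed through named child streams, so the
whole dataset is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .corpus import (AnnotatedToken, ParseTree, canonical_morph,
                     compute_closing_nodes, filter_content_words,
                     make_integral_stream, make_syntactic_stream)
from .encoding import BoldRun, HrfSpec, WordEventSeries, make_design
from .grids import VoxelGrid

__all__ = ["SimConfig", "GroundTruthManifest", "SimDataset", "gen_corpus",
           "gen_feature_factors", "gen_bold", "generate_dataset",
           "write_fixture_tree"]

# ---------------------------------------------------------------------------
# vocabulary and template grammar

_NOUNS = [
    "cat", "dog", "bird", "horse", "fox", "river", "mountain", "garden",
    "house", "window", "door", "road", "forest", "flower", "stone", "cloud",
    "child", "farmer", "sailor", "teacher", "doctor", "painter", "king",
    "queen", "soldier", "baker", "letter", "book", "song", "story", "ship",
    "train", "bridge", "castle", "village", "market", "lantern", "mirror",
    "clock", "candle",
]
_VERBS = [  # (past, pres-3sg)
    ("chased", "chases"), ("watched", "watches"), ("followed", "follows"),
    ("painted", "paints"), ("carried", "carries"), ("opened", "opens"),
    ("closed", "closes"), ("crossed", "crosses"), ("visited", "visits"),
    ("repaired", "repairs"), ("admired", "admires"), ("remembered", "remembers"),
    ("described", "describes"), ("greeted", "greets"), ("counted", "counts"),
    ("lifted", "lifts"),
]
_ADJS = ["old", "young", "quiet", "bright", "heavy", "gentle", "narrow",
         "golden", "distant", "small", "tall", "pale"]
_ADVS = ["slowly", "quickly", "quietly", "carefully", "suddenly", "gladly",
         "often", "rarely"]
_DETS = [("the", "Definite=Def|PronType=Art"), ("a", "Definite=Ind|PronType=Art")]
_PREPS = ["near", "behind", "beyond", "under"]

_DET_POS, _NOUN_POS, _VERB_POS = "DET", "NOUN", "VERB"


def _sample_noun(rng):
    lemma = _NOUNS[rng.integers(len(_NOUNS))]
    if rng.random() < 0.5:
        return (lemma, "NOUN", "Number=Sing", "NN")
    return (lemma + "s", "NOUN", "Number=Plur", "NNS")


def _sample_verb(rng):
    past, pres = _VERBS[rng.integers(len(_VERBS))]
    if rng.random() < 0.5:
        return (past, "VERB", "Tense=Past|VerbForm=Fin", "VBD")
    return (pres, "VERB", "Mood=Ind|Number=Sing|Person=3|Tense=Pres", "VBZ")


def _sample_det(rng):
    form, feats = _DETS[rng.integers(len(_DETS))]
    return (form, "DET", feats, "DT")


def _sample_adj(rng):
    return (_ADJS[rng.integers(len(_ADJS))], "ADJ", "Degree=Pos", "JJ")


def _sample_adv(rng):
    return (_ADVS[rng.integers(len(_ADVS))], "ADV", "_", "RB")


def _sample_prep(rng):
    return (_PREPS[rng.integers(len(_PREPS))], "ADP", "_", "IN")


_PUNCT = (".", "PUNCT", "_", ".")


def _np(rng, with_adj=False):
    det = _sample_det(rng)
    if with_adj:
        adj = _sample_adj(rng)
        noun = _sample_noun(rng)
        return ("NP", [("DT", det), ("JJ", adj), (noun[3], noun)]), [det, adj, noun]
    noun = _sample_noun(rng)
    return ("NP", [("DT", det), (noun[3], noun)]), [det, noun]


def _template_transitive(rng):
    np1, t1 = _np(rng)
    verb = _sample_verb(rng)
    np2, t2 = _np(rng)
    tree = ("S", [np1, ("VP", [(verb[3], verb), np2]), (".", _PUNCT)])
    return tree, t1 + [verb] + t2 + [_PUNCT]


def _template_adjectival(rng):
    np1, t1 = _np(rng, with_adj=True)
    verb = _sample_verb(rng)
    np2, t2 = _np(rng, with_adj=True)
    tree = ("S", [np1, ("VP", [(verb[3], verb), np2]), (".", _PUNCT)])
    return tree, t1 + [verb] + t2 + [_PUNCT]


def _template_pp(rng):
    np1, t1 = _np(rng)
    verb = _sample_verb(rng)
    prep = _sample_prep(rng)
    np2, t2 = _np(rng)
    tree = ("S", [np1, ("VP", [(verb[3], verb),
                               ("PP", [("IN", prep), np2])]), (".", _PUNCT)])
    return tree, t1 + [verb, prep] + t2 + [_PUNCT]


def _template_adverbial(rng):
    np1, t1 = _np(rng)
    verb = _sample_verb(rng)
    adv = _sample_adv(rng)
    tree = ("S", [np1, ("VP", [(verb[3], verb), ("RB", adv)]), (".", _PUNCT)])
    return tree, t1 + [verb, adv, _PUNCT]


# (builder, content tokens, total tokens) — counts drive the ratio solver
_TEMPLATES = [
    (_template_transitive, 3, 6),
    (_template_adjectival, 5, 8),
    (_template_pp, 3, 7),
    (_template_adverbial, 3, 5),
]


def _template_probs(target_fraction: float) -> np.ndarray:
    """Template mixture whose expected content-word fraction hits the target."""
    c = np.array([t[1] for t in _TEMPLATES], dtype=float)
    n = np.array([t[2] for t in _TEMPLATES], dtype=float)
    p0 = np.full(len(_TEMPLATES), 1.0 / len(_TEMPLATES))
    ratios = c / n
    f0 = (p0 @ c) / (p0 @ n)
    if abs(target_fraction - f0) < 1e-12:
        return p0
    k = int(np.argmax(ratios)) if target_fraction > f0 else int(np.argmin(ratios))
    e = np.zeros_like(p0); e[k] = 1.0
    c0, n0, ck, nk = p0 @ c, p0 @ n, c[k], n[k]
    denom = (c0 - ck) + target_fraction * (nk - n0)
    lam = (c0 - target_fraction * n0) / denom
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"content fraction {target_fraction} outside the "
                         f"grammar's reachable range [{ratios.min():.3f}, "
                         f"{ratios.max():.3f}]")
    return (1 - lam) * p0 + lam * e


def _tree_to_bracketed(node) -> str:
    label, children = node
    parts = []
    for child in children:
        if isinstance(child[1], tuple):  # preterminal: (ptb_tag, token)
            tag, tok = child
            parts.append(f"({tag} {tok[0]})")
        else:
            parts.append(_tree_to_bracketed(child))
    return f"({label} {' '.join(parts)})"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    The defaults define the standard cohort: 20 subjects, nine runs of 300+
    tokens at TR = 2 s, 700 voxels on a 4 mm lattice, per-voxel SNR 1.0
    (signal variance over noise variance) with AR(1) noise.
    """

    n_runs: int = 9
    tokens_per_run: int = 300
    tr: float = 2.0
    n_subjects: int = 20
    word_dur: tuple = (0.20, 0.40)
    word_gap: tuple = (0.10, 0.30)
    punct_dur: tuple = (0.05, 0.10)
    content_fraction: float = 0.5
    d_sem: int = 8
    d_syn: int = 8
    n_products: int = 4
    d_ctx: int = 8
    ctx_decays: dict = field(default_factory=lambda: {5: 0.55, 15: 0.88})
    snr: float = 1.0
    ar_coef: float = 0.3
    weight_jitter: float = 0.2
    class_counts: dict = field(default_factory=lambda: {
        "semantic": 40, "syntactic": 40, "mixed": 40, "interaction": 110,
        "context5": 35, "context15": 35, "null": 400,
    })
    grid_shape: tuple = (10, 10, 9)
    gap_layers: tuple = (3, 4)
    voxel_size_mm: float = 4.0
    run_padding_s: float = 20.0
    seed: int = 1

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be nonnegative")
        if any(not 0 < g < 1 for g in self.ctx_decays.values()):
            raise ValueError("context decays must lie in (0, 1)")
        if self.d_ctx % len(self.ctx_decays) != 0:
            raise ValueError("d_ctx must divide evenly across context channels")


#: which hemisphere each planted class prefers (see module docstring)
_CLASS_HEMISPHERE = {
    "semantic": "L", "syntactic": "L", "context15": "L", "context5": "L",
    "mixed": "R", "interaction": "R",
}

#: which factor block drives each planted class
_CLASS_SPACE = {
    "semantic": "sem", "syntactic": "syn", "mixed": ("sem", "syn"),
    "interaction": "prod", "context5": "ctx5", "context15": "ctx15",
}


@dataclass
class GroundTruthManifest:
    """Planted truth: per-voxel class, hemisphere and generative weights."""

    classes: np.ndarray                 # (n_voxels,) str
    hemisphere: np.ndarray              # (n_voxels,) {"L","R"}
    weights: dict                       # voxel index -> base weight vector
    class_counts: dict
    expected_model: dict = field(default_factory=lambda: {
        "semantic": "semantic", "syntactic": "syntactic", "mixed": "concat",
        "interaction": "integral", "context5": "ctx5", "context15": "ctx15",
    })

    def voxels_of(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls)

    def to_json(self) -> str:
        return json.dumps({
            "classes": self.classes.tolist(),
            "hemisphere": self.hemisphere.tolist(),
            "class_counts": {k: int(v) for k, v in self.class_counts.items()},
            "expected_model": self.expected_model,
            "weights": {str(k): np.asarray(v).tolist()
                        for k, v in self.weights.items()},
        }, indent=1)


@dataclass
class SimDataset:
    """Everything the pipeline needs, plus the planted truth."""

    cfg: SimConfig
    tokens: list
    trees: list
    timings: pd.DataFrame
    factors: "FactorSet"
    grid: VoxelGrid
    manifest: GroundTruthManifest
    bold: dict                      # subject id -> list[BoldRun]
    audio_rms: list                 # per run: (times, values)
    scan_times: list                # per run: np.ndarray


# ---------------------------------------------------------------------------
# corpus generation


def gen_corpus(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Template-grammar corpus: tokens with annotations, trees, timings.

    Each run is an independent sequence of sentences; generation stops at
    the first sentence boundary at or past ``tokens_per_run`` tokens, so
    trees always align with complete sentences.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    probs = _template_probs(cfg.content_fraction)
    tokens: list[AnnotatedToken] = []
    trees: list[ParseTree] = []
    rows = []
    for run in range(1, cfg.n_runs + 1):
        t = 0.0
        n_in_run = 0
        while n_in_run < cfg.tokens_per_run:
            builder = _TEMPLATES[rng.choice(len(_TEMPLATES), p=probs)][0]
            tree_node, sent_tokens = builder(rng)
            trees.append(ParseTree(_tree_to_bracketed(tree_node)))
            for form, upos, feats, _ptb in sent_tokens:
                lo, hi = cfg.punct_dur if upos == "PUNCT" else cfg.word_dur
                dur = rng.uniform(lo, hi)
                onset, offset = t, t + dur
                t = offset + rng.uniform(*cfg.word_gap)
                tokens.append(AnnotatedToken(
                    form=form, pos=upos, morph=feats,
                    is_punct=(upos == "PUNCT"),
                    onset=onset, offset=offset, run_id=run))
                rows.append((form, onset, offset, run))
                n_in_run += 1
    timings = pd.DataFrame(rows, columns=["token", "onset", "offset", "run"])
    return tokens, trees, timings


# ---------------------------------------------------------------------------
# latent factors


@dataclass
class FactorSet:
    """Per-token latent factors and the symbol tables they come from."""

    sem_table: dict                 # content word form -> (d_sem,)
    syn_table: dict                 # triplet symbol -> (d_syn,)
    ctx_table: dict                 # any surface form -> (d_ctx,)
    sem_tok: np.ndarray             # (w, d_sem); zero rows at non-content tokens
    syn_tok: np.ndarray             # (w, d_syn)
    prod_tok: np.ndarray            # (w, n_products)
    ctx_avg: dict                   # window k -> (w, d_ctx)
    streams: dict                   # mode -> FeatureStream
    vocab: object                   # SyntacticVocabulary
    ncn: list


def _decayed_average(vectors: np.ndarray, run_ids: np.ndarray, window: int,
                     decay: float) -> np.ndarray:
    """Decaying average over a hard window of past tokens, per run."""
    w, d = vectors.shape
    weights = decay ** np.arange(window)
    out = np.empty_like(vectors)
    for run in np.unique(run_ids):
        pos = np.flatnonzero(run_ids == run)
        v = vectors[pos]
        for i in range(len(pos)):
            lo = max(0, i - window + 1)
            ws = weights[:i - lo + 1]
            out[pos[i]] = (ws[::-1] @ v[lo:i + 1]) / ws.sum()
    return out


def gen_feature_factors(cfg: SimConfig, tokens, trees,
                        rng: np.random.Generator | None = None) -> FactorSet:
    """Latent semantic/syntactic factor vectors, orthogonal in expectation.

    Semantic factors depend only on the content word's identity; syntactic
    factors only on the (POS, Morph, NCN) triplet; drawn from independent
    streams so their empirical cross-correlation vanishes at large n.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    ncn: list[int] = []
    for tree in trees:
        ncn.extend(compute_closing_nodes(tree))
    if len(ncn) != len(tokens):
        raise ValueError("trees and tokens disagree on token count")

    sem_stream = filter_content_words(tokens)
    syn_stream, vocab = make_syntactic_stream(tokens, ncn)
    int_stream = make_integral_stream(tokens)

    def table(symbols, d, gen):
        return {s: gen.standard_normal(d) / np.sqrt(d) for s in sorted(set(symbols))}

    rng_sem, rng_syn, rng_ctx = [np.random.default_rng(s)
                                 for s in rng.bit_generator.seed_seq.spawn(3)]
    sem_table = table(sem_stream.symbols, cfg.d_sem, rng_sem)
    syn_table = table(syn_stream.symbols, cfg.d_syn, rng_syn)
    ctx_table = table(int_stream.symbols, cfg.d_ctx, rng_ctx)

    # a word deterministically carries its (POS, Morph) signature, which
    # would correlate the two spaces; centering semantic vectors within each
    # signature group makes E[sem factor | syntactic category] = 0, i.e. the
    # spaces are orthogonal in expectation as the restriction design intends
    signature: dict[str, tuple] = {}
    for tok in tokens:
        if tok.form in sem_table:
            signature.setdefault(tok.form, (tok.pos, tok.morph))
    groups: dict[tuple, list[str]] = {}
    for form, sig in signature.items():
        groups.setdefault(sig, []).append(form)
    for forms in groups.values():
        mean = np.mean([sem_table[fm] for fm in forms], axis=0)
        if len(forms) > 1:
            for fm in forms:
                sem_table[fm] = sem_table[fm] - mean

    w = len(tokens)
    sem_tok = np.zeros((w, cfg.d_sem))
    for pos, src in zip(sem_stream.symbols, sem_stream.alignment):
        sem_tok[src] = sem_table[pos]
    syn_tok = np.vstack([syn_table[s] for s in syn_stream.symbols])
    k = cfg.n_products
    prod_tok = sem_tok[:, :k] * syn_tok[:, :k] * np.sqrt(cfg.d_sem)

    # context channels: each window length k owns a block of d_ctx /
    # n_channels base dimensions, averaged with its own decay over a hard
    # window of k tokens (effective window ~ k because decay^k is small)
    ctx_vecs = np.vstack([ctx_table[s] for s in int_stream.symbols])
    run_ids = np.array([t.run_id for t in tokens])
    windows = sorted(cfg.ctx_decays)
    block = cfg.d_ctx // len(windows)
    ctx_avg = {}
    for ci, kk in enumerate(windows):
        vecs = ctx_vecs[:, ci * block:(ci + 1) * block]
        ctx_avg[kk] = _decayed_average(vecs, run_ids, kk, cfg.ctx_decays[kk])
    return FactorSet(sem_table=sem_table, syn_table=syn_table,
                     ctx_table=ctx_table, sem_tok=sem_tok, syn_tok=syn_tok,
                     prod_tok=prod_tok, ctx_avg=ctx_avg,
                     streams={"semantic": sem_stream, "syntactic": syn_stream,
                              "integral": int_stream},
                     vocab=vocab, ncn=ncn)


# ---------------------------------------------------------------------------
# grid / class layout


def _build_grid(cfg: SimConfig) -> tuple[VoxelGrid, np.ndarray]:
    """Voxel lattice with a two-layer gap; returns grid and class labels."""
    nx, ny, nz = cfg.grid_shape
    gap = set(cfg.gap_layers)
    coords, hemi = [], []
    keys = []
    for k in range(nz):
        if k in gap:
            continue
        for j in range(ny):
            for i in range(nx):
                x = (i - (nx - 1) / 2.0) * cfg.voxel_size_mm
                y = (j - (ny - 1) / 2.0) * cfg.voxel_size_mm
                z = k * cfg.voxel_size_mm
                coords.append((x, y, z))
                hemi.append("L" if x < 0 else "R")
                keys.append((k, j, i))
    coords = np.array(coords)
    hemi = np.array(hemi)
    grid = VoxelGrid(coords=coords, hemisphere=hemi)

    max_gap = max(gap)
    planted_zone = np.array([k < min(gap) for (k, j, i) in keys])
    null_zone = ~planted_zone
    classes = np.full(len(keys), "null", dtype=object)

    counts = dict(cfg.class_counts)
    n_null_cfg = counts.pop("null", int(null_zone.sum()))
    planted_total = sum(counts.values())
    if planted_total != int(planted_zone.sum()) or n_null_cfg != int(null_zone.sum()):
        raise ValueError(
            f"class counts ({planted_total} planted + {n_null_cfg} null) do not "
            f"fill the lattice ({int(planted_zone.sum())} planted-zone + "
            f"{int(null_zone.sum())} null-zone voxels)")

    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    left_slots = [v for v in order if planted_zone[v] and hemi[v] == "L"]
    right_slots = [v for v in order if planted_zone[v] and hemi[v] == "R"]
    slots = {"L": left_slots, "R": right_slots}
    leftovers = []
    for cls, n in counts.items():
        pref = _CLASS_HEMISPHERE.get(cls, "L")
        take = min(n, len(slots[pref]))
        for v in slots[pref][:take]:
            classes[v] = cls
        slots[pref] = slots[pref][take:]
        if take < n:
            leftovers.append((cls, n - take))
    spill = slots["L"] + slots["R"]
    for cls, n in leftovers:
        for v in spill[:n]:
            classes[v] = cls
        spill = spill[n:]
    return grid, classes.astype(str)


# ---------------------------------------------------------------------------
# BOLD generation


def _ar1_noise(rng, n_scans: int, n_vox: int, coef: float) -> np.ndarray:
    """Stationary AR(1) noise, unit marginal variance."""
    burn = 50
    e = rng.standard_normal((n_scans + burn, n_vox)) * np.sqrt(1 - coef ** 2)
    from scipy.signal import lfilter
    x = lfilter([1.0], [1.0, -coef], e, axis=0)
    return x[burn:]


def _synth_audio_rms(tokens_run, run_dur: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 10 ms acoustic-energy series: loud during words, near-silent between."""
    times = np.arange(0.0, run_dur, 0.01)
    values = np.full(times.shape, 0.01)
    for tok in tokens_run:
        sel = (times >= tok.onset) & (times < tok.offset)
        values[sel] = 0.3 + 0.2 * rng.random()
    return times, values


def gen_bold(cfg: SimConfig, factors: FactorSet, tokens, grid: VoxelGrid,
             classes: np.ndarray, rng: np.random.Generator):
    """Multi-subject BOLD runs with planted voxel classes.

    Each planted voxel's noiseless series is the HRF-convolved projection of
    its class's factor block onto a voxel-specific weight vector, scaled so
    that signal variance / noise variance equals the configured SNR (the
    ``mixed`` class carries *two* components, each at that SNR).  AR(1)
    Gaussian noise of unit variance is added.  Subjects share the class
    structure and base weights; each subject's weights are jittered and its
    noise is independent.
    """
    spec = HrfSpec()
    run_ids = np.array([t.run_id for t in tokens])
    offsets = np.array([t.offset for t in tokens])

    blocks = {"sem": factors.sem_tok, "syn": factors.syn_tok,
              "prod": factors.prod_tok, "ctx5": factors.ctx_avg[5],
              "ctx15": factors.ctx_avg[15]}

    scan_times, conv = [], {name: [] for name in blocks}
    runs = sorted(np.unique(run_ids))
    for run in runs:
        sel = run_ids == run
        run_dur = offsets[sel].max() + cfg.run_padding_s
        n_scans = int(np.ceil(run_dur / cfg.tr))
        st = np.arange(n_scans) * cfg.tr
        scan_times.append(st)
        for name, block in blocks.items():
            ev = WordEventSeries(times=offsets[sel], amplitudes=block[sel], run_id=run)
            conv[name].append(make_design(ev, spec, st, tr=cfg.tr))

    block = cfg.d_ctx // len(cfg.ctx_decays)
    dims = {"sem": cfg.d_sem, "syn": cfg.d_syn, "prod": cfg.n_products,
            "ctx5": block, "ctx15": block}
    seed_seq = rng.bit_generator.seed_seq
    rng_w, rng_sub = [np.random.default_rng(s) for s in seed_seq.spawn(2)]

    base_weights: dict[int, np.ndarray] = {}
    for v in range(grid.n_voxels):
        cls = classes[v]
        if cls == "null":
            continue
        space = _CLASS_SPACE[cls]
        if isinstance(space, tuple):
            w = np.concatenate([_unit(rng_w.standard_normal(dims[s])) for s in space])
        else:
            w = _unit(rng_w.standard_normal(dims[space]))
        base_weights[v] = w

    def _noiseless(weights: dict[int, np.ndarray]) -> list[np.ndarray]:
        """Per-run (scans × voxels) noiseless signal for the given weights."""
        out = []
        for ri in range(len(runs)):
            sig = np.zeros((scan_times[ri].shape[0], grid.n_voxels))
            out.append(sig)
        for v, w in weights.items():
            space = _CLASS_SPACE[classes[v]]
            parts = space if isinstance(space, tuple) else (space,)
            off = 0
            comps = []
            for s in parts:
                comps.append((s, w[off:off + dims[s]]))
                off += dims[s]
            # rescale each component to the target SNR using the full series
            for s, ws in comps:
                full = np.concatenate([conv[s][ri] @ ws for ri in range(len(runs))])
                var = full.var()
                scale = np.sqrt(cfg.snr / var) if var > 0 else 0.0
                ws *= scale
            for ri in range(len(runs)):
                total = np.zeros(scan_times[ri].shape[0])
                for s, ws in comps:
                    total = total + conv[s][ri] @ ws
                out[ri][:, v] = total
        return out

    bold: dict[str, list[BoldRun]] = {}
    for s_idx in range(cfg.n_subjects):
        sub_rng = np.random.default_rng(rng_sub.bit_generator.seed_seq.spawn(1)[0])
        sub_weights = {
            v: w + cfg.weight_jitter * sub_rng.standard_normal(w.shape)
            for v, w in base_weights.items()
        }
        signal = _noiseless(sub_weights)
        subject = f"sub-{s_idx + 1:02d}"
        runs_out = []
        for ri, run in enumerate(runs):
            noise = _ar1_noise(sub_rng, scan_times[ri].shape[0], grid.n_voxels,
                               cfg.ar_coef)
            runs_out.append(BoldRun(data=signal[ri] + noise, tr=cfg.tr,
                                    subject=subject, run_id=int(run), grid=grid))
        bold[subject] = runs_out

    manifest = GroundTruthManifest(
        classes=classes, hemisphere=grid.hemisphere,
        weights=base_weights,
        class_counts={c: int(np.sum(classes == c))
                      for c in sorted(set(classes.tolist()))},
    )
    return bold, manifest, scan_times


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def load_config(path) -> SimConfig:
    """Read a SimConfig from a JSON key-value file (documented schema =
    the SimConfig field names; unknown keys are rejected)."""
    raw = json.loads(Path(path).read_text())
    fields = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "ctx_decays" in raw:
        raw["ctx_decays"] = {int(k): float(v) for k, v in raw["ctx_decays"].items()}
    for key in ("grid_shape", "gap_layers", "word_dur", "word_gap", "punct_dur"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


def generate_dataset(cfg: SimConfig | None = None) -> SimDataset:
    """Generate the complete synthetic study from one seed."""
    if cfg is None:
        cfg = SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    s_corpus, s_factors, s_bold, s_audio = root.spawn(4)
    tokens, trees, timings = gen_corpus(cfg, np.random.default_rng(s_corpus))
    factors = gen_feature_factors(cfg, tokens, trees, np.random.default_rng(s_factors))
    grid, classes = _build_grid(cfg)
    bold, manifest, scan_times = gen_bold(cfg, factors, tokens, grid, classes,
                                          np.random.default_rng(s_bold))
    rng_audio = np.random.default_rng(s_audio)
    audio = []
    run_ids = np.array([t.run_id for t in tokens])
    for ri, run in enumerate(sorted(np.unique(run_ids))):
        toks_run = [t for t in tokens if t.run_id == run]
        run_dur = scan_times[ri][-1] + cfg.tr
        audio.append(_synth_audio_rms(toks_run, run_dur, rng_audio))
    return SimDataset(cfg=cfg, tokens=tokens, trees=trees, timings=timings,
                      factors=factors, grid=grid, manifest=manifest, bold=bold,
                      audio_rms=audio, scan_times=scan_times)


def write_fixture_tree(ds: SimDataset, outdir) -> None:
    """Write the dataset as the plain-text fixture tree the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sentences, sent = [], []
    boundary = 0
    for tree in ds.trees:
        n = len(tree.leaves())
        sent = [(t.form, t.pos, t.morph) for t in ds.tokens[boundary:boundary + n]]
        sentences.append(sent)
        boundary += n
    (out / "annotations.conllu").write_text(_io.format_conllu(sentences))
    (out / "trees.txt").write_text(_io.format_trees(ds.trees))
    _io.write_timings(ds.timings, out / "timings.tsv")
    _io.write_grid(ds.grid, out / "grid.tsv")
    (out / "manifest.json").write_text(ds.manifest.to_json())
    for subject, runs in ds.bold.items():
        for run in runs:
            _io.write_bold_run(run.data, out / f"{subject}_run-{run.run_id}.tsv",
                               tr=run.tr, subject=subject, run_id=run.run_id)
    for ri, (t, v) in enumerate(ds.audio_rms, start=1):
        pd.DataFrame({"time": t, "rms": v}).to_csv(
            out / f"audio_rms_run-{ri}.tsv", sep="\t", index=False)
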