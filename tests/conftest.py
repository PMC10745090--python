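"""Shared fixtures and oracle helpers."""

import numpy as np
import pytest

from semsyn.corpus import AnnotatedToken, ParseTree


def make_tokens(specs, run_id=1, start=0.0):
    """Build AnnotatedTokens from (form, pos[, morph]) tuples with timings."""
    toks = []
    t = start
    for s in specs:
        form, pos = s[0], s[1]
        morph = s[2] if len(s) > 2 else "_"
        toks.append(AnnotatedToken(form=form, pos=pos, morph=morph,
                                   is_punct=(pos == "PUNCT"),
                                   onset=t, offset=t + 0.3, run_id=run_id))
        t += 0.5
    return toks


def random_tree(rng, max_depth=4, max_children=3):
    """Random labelled tree; leaves are preterminal+word pairs."""
    counter = [0]

    def node(depth):
        counter[0] += 1
        label = f"N{counter[0]}"
        if depth >= max_depth or rng.random() < 0.3:
            counter[0] += 1
            return f"({label} (P{counter[0]} w{counter[0]}))"
        n = rng.integers(1, max_children + 1)
        kids = " ".join(node(depth + 1) for _ in range(n))
        return f"({label} {kids})"

    return ParseTree(node(0))


def ncn_bracket_oracle(bracketed: str) -> list[int]:
    """Count closing brackets immediately following each leaf token.

    A leaf is a non-bracket token whose predecessor is also a non-bracket
    token (its preterminal label), in a canonical one-word-per-preterminal
    bracketed string.
    """
    import re
    toks = re.findall(r"\(|\)|[^\s()]+", bracketed)
    out = []
    for i, t in enumerate(toks):
        if t in "()" or i == 0 or toks[i - 1] in "()":
            continue
        n = 0
        j = i + 1
        while j < len(toks) and toks[j] == ")":
            n += 1
            j += 1
        out.append(n)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_dataset():
    """A miniature cohort for fast end-to-end checks."""
    from semsyn.simulate import SimConfig, generate_dataset
    cfg = SimConfig(
        n_runs=4, tokens_per_run=80, n_subjects=4,
        class_counts={"semantic": 10, "syntactic": 10, "mixed": 10,
                      "interaction": 14, "context5": 8, "context15": 8,
                      "null": 60},
        grid_shape=(5, 6, 6), gap_layers=(2, 3), seed=11,
    )
    return generate_dataset(cfg)
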