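"""Information-restricted feature streams from annotated text.

The analysis dissociates *what is said* from *how it is said* by splitting
an annotated token stream into three views:

* **integral** — every token (words and punctuation) as-is;
* **semantic** — only open-class (content) words, everything else removed;
* **syntactic** — every token replaced by an identifier encoding the
  triplet (POS, morphological bundle, NCN), where NCN is the number of
  constituency-tree nodes that close at that token.

Each view is a :class:`FeatureStream` that remembers which original token
every stream position came from, so downstream regressors can be placed at
the right word timings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "UPOS_TAGS", "CONTENT_POS", "AnnotatedToken", "ParseTree",
    "SyntacticVocabulary", "FeatureStream", "AlignmentError", "TreeFormatError",
    "read_annotations", "compute_closing_nodes", "filter_content_words",
    "make_syntactic_stream", "make_integral_stream", "canonical_morph",
    "triplet_symbol",
]

#: The closed set of Universal POS tags accepted on input.
UPOS_TAGS = frozenset({
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
})

#: Open-class tags retained in the semantic stream (standard open/closed split).
CONTENT_POS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV", "NUM", "INTJ"})


class AlignmentError(ValueError):
    """Token counts disagree across annotation sources."""


class TreeFormatError(ValueError):
    """A bracketed tree string is malformed."""


class ConfigurationError(ValueError):
    """An annotation uses a tag outside the configured closed set."""


def canonical_morph(feats: str | None) -> str:
    """Canonical sorted ``Feat=Val|...`` serialization; empty bundle -> ``_``."""
    if feats is None or feats in ("", "_"):
        return "_"
    parts = sorted(p.strip() for p in feats.split("|") if p.strip())
    return "|".join(parts) if parts else "_"


@dataclass(frozen=True)
class AnnotatedToken:
    """One stimulus token with its annotations and timing."""

    form: str
    pos: str
    morph: str = "_"
    is_punct: bool = False
    onset: float = 0.0
    offset: float = 0.0
    run_id: int = 1

    def __post_init__(self):
        if self.pos not in UPOS_TAGS:
            raise ConfigurationError(f"unknown POS tag {self.pos!r} for token {self.form!r}")
        if not self.offset > self.onset:
            raise ValueError(f"token {self.form!r}: offset must exceed onset")
        object.__setattr__(self, "morph", canonical_morph(self.morph))


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class ParseTree:
    """A PTB-style bracketed constituency tree for one sentence.

    Internally stored as ``(label, children)`` tuples; a leaf is a plain
    string (the word form), and its parent is the preterminal node.
    """

    def __init__(self, bracketed: str):
        self.bracketed = bracketed.strip()
        self.root = self._parse(self.bracketed)

    @staticmethod
    def _parse(text: str):
        toks = _TOKEN_RE.findall(text)
        if not toks:
            raise TreeFormatError("empty tree string")
        pos = 0

        def parse_node():
            nonlocal pos
            if toks[pos] != "(":
                raise TreeFormatError(f"expected '(' at token {pos} of {text!r}")
            pos += 1
            if pos >= len(toks) or toks[pos] in "()":
                raise TreeFormatError(f"missing node label in {text!r}")
            label = toks[pos]
            pos += 1
            children = []
            while pos < len(toks) and toks[pos] != ")":
                if toks[pos] == "(":
                    children.append(parse_node())
                else:
                    children.append(toks[pos])
                    pos += 1
            if pos >= len(toks):
                raise TreeFormatError(f"unbalanced brackets in {text!r}")
            pos += 1  # consume ')'
            if not children:
                raise TreeFormatError(f"node {label!r} has no children in {text!r}")
            return (label, children)

        root = parse_node()
        if pos != len(toks):
            raise TreeFormatError(f"trailing material after root in {text!r}")
        return root

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            if isinstance(node, str):
                out.append(node)
                return
            for child in node[1]:
                walk(child)

        walk(self.root)
        return out

    def n_nodes(self) -> int:
        """Number of labelled nodes (preterminals and root included)."""

        def count(node):
            if isinstance(node, str):
                return 0
            return 1 + sum(count(c) for c in node[1])

        return count(self.root)

    def __repr__(self):
        return f"ParseTree({self.bracketed!r})"


def compute_closing_nodes(tree: ParseTree) -> list[int]:
    """Number of tree nodes closing at each leaf (NCN).

    A node "closes" at its last leaf; equivalently, NCN of a leaf is the
    run of closing brackets immediately following it in the bracketed
    string.  Summed over leaves this equals the total node count, since
    every node closes at exactly one leaf.
    """
    ncn: list[int] = []

    def walk(node) -> int:
        """Return index of the node's last leaf; credit the node to it."""
        if isinstance(node, str):
            ncn.append(0)
            return len(ncn) - 1
        last = -1
        for child in node[1]:
            last = walk(child)
        ncn[last] += 1
        return last

    walk(tree.root)
    return ncn


@dataclass
class SyntacticVocabulary:
    """Dense, stable mapping from (POS, Morph, NCN) triplets to integer ids."""

    triplet_to_id: dict[tuple[str, str, int], int]
    oov_id: int

    @classmethod
    def build(cls, triplets) -> "SyntacticVocabulary":
        mapping: dict[tuple[str, str, int], int] = {}
        for t in triplets:
            if t not in mapping:
                mapping[t] = len(mapping)
        return cls(triplet_to_id=mapping, oov_id=len(mapping))

    def __len__(self) -> int:
        return len(self.triplet_to_id)

    def lookup(self, triplet: tuple[str, str, int]) -> int:
        return self.triplet_to_id.get(triplet, self.oov_id)


def triplet_symbol(pos: str, morph: str, ncn: int) -> str:
    """Human-readable stream symbol for a syntactic triplet."""
    return f"{pos}|{morph}|{ncn}"


@dataclass
class FeatureStream:
    """An ordered feature view of the token stream.

    ``symbols[i]`` is the i-th stream item and ``alignment[i]`` the index of
    the original token it came from (injective, strictly increasing).
    """

    mode: str
    symbols: list[str]
    alignment: list[int]

    def __post_init__(self):
        if self.mode not in ("integral", "semantic", "syntactic"):
            raise ValueError(f"unknown stream mode {self.mode!r}")
        if len(self.symbols) != len(self.alignment):
            raise ValueError("symbols and alignment lengths differ")
        if any(b <= a for a, b in zip(self.alignment, self.alignment[1:])):
            raise ValueError("alignment must be strictly increasing")

    def __len__(self) -> int:
        return len(self.symbols)


def read_annotations(conllu_text: str, trees: list[ParseTree],
                     timings: pd.DataFrame) -> list[AnnotatedToken]:
    """Join CoNLL-U annotations, parse trees and word timings into tokens.

    Parameters
    ----------
    conllu_text : str
        CoNLL-U text; only FORM, UPOS and FEATS columns are consumed.
    trees : list of ParseTree
        One per sentence, leaf order matching the sentence's tokens.
    timings : DataFrame
        Columns ``token``, ``onset``, ``offset``, ``run`` — one row per
        token across the whole stimulus, in stream order.
    """
    from . import io as _io

    sentences = _io.parse_conllu(conllu_text)
    if len(sentences) != len(trees):
        raise AlignmentError(
            f"{len(sentences)} CoNLL-U sentences but {len(trees)} trees")
    n_tokens = sum(len(s) for s in sentences)
    if n_tokens != len(timings):
        raise AlignmentError(
            f"{n_tokens} annotated tokens but {len(timings)} timing rows")

    tokens: list[AnnotatedToken] = []
    cursor = 0
    for si, (sent, tree) in enumerate(zip(sentences, trees)):
        leaves = tree.leaves()
        if len(leaves) != len(sent):
            raise AlignmentError(
                f"sentence {si}: {len(sent)} tokens but tree has {len(leaves)} leaves")
        for (form, upos, feats), leaf in zip(sent, leaves):
            row = timings.iloc[cursor]
            if str(row["token"]) != form:
                raise AlignmentError(
                    f"sentence {si}: token {form!r} does not match timing row "
                    f"{row['token']!r} at position {cursor}")
            tokens.append(AnnotatedToken(
                form=form, pos=upos, morph=feats,
                is_punct=(upos == "PUNCT"),
                onset=float(row["onset"]), offset=float(row["offset"]),
                run_id=int(row["run"]),
            ))
            cursor += 1
    return tokens


def filter_content_words(tokens: list[AnnotatedToken],
                         content_pos: frozenset = CONTENT_POS) -> FeatureStream:
    """Semantic stream: keep only content words, in original order."""
    for tok in tokens:
        if tok.pos not in UPOS_TAGS:
            raise ConfigurationError(f"unknown POS tag {tok.pos!r}")
    kept = [(tok.form, i) for i, tok in enumerate(tokens) if tok.pos in content_pos]
    return FeatureStream(
        mode="semantic",
        symbols=[s for s, _ in kept],
        alignment=[i for _, i in kept],
    )


def make_integral_stream(tokens: list[AnnotatedToken]) -> FeatureStream:
    """Integral stream: one symbol (the surface form) per token."""
    return FeatureStream(
        mode="integral",
        symbols=[t.form for t in tokens],
        alignment=list(range(len(tokens))),
    )


def make_syntactic_stream(tokens: list[AnnotatedToken], ncn: list[int],
                          vocab: SyntacticVocabulary | None = None,
                          ) -> tuple[FeatureStream, SyntacticVocabulary]:
    """Syntactic stream: one triplet identifier per token.

    When ``vocab`` is given, unseen triplets map to its ``oov_id``;
    otherwise a vocabulary is built from the input.
    """
    if len(ncn) != len(tokens):
        raise AlignmentError(f"{len(tokens)} tokens but {len(ncn)} NCN values")
    triplets = [(t.pos, t.morph, int(n)) for t, n in zip(tokens, ncn)]
    if vocab is None:
        vocab = SyntacticVocabulary.build(triplets)
    # symbols carry the triplet text; ids are recoverable through the vocab
    symbols = [triplet_symbol(*t) if t in vocab.triplet_to_id else "OOV"
               for t in triplets]
    stream = FeatureStream(mode="syntactic", symbols=symbols,
                           alignment=list(range(len(tokens))))
    return stream, vocab


def stream_ids(stream: FeatureStream, tokens: list[AnnotatedToken],
               ncn: list[int], vocab: SyntacticVocabulary) -> list[int]:
    """Integer triplet ids for a syntactic stream (OOV -> ``vocab.oov_id``)."""
    return [vocab.lookup((tokens[i].pos, tokens[i].morph, int(ncn[i])))
            for i in stream.alignment]
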