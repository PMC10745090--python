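"""Restricting an annotated sentence into semantic and syntactic streams.

Builds a tiny annotated stimulus, computes per-token closing-node counts
from the constituency trees, and prints the three feature views.
"""

from semsyn.corpus import (AnnotatedToken, ParseTree, compute_closing_nodes,
                           filter_content_words, make_integral_stream,
                           make_syntactic_stream)

trees = [ParseTree("(S (NP (DT The) (JJ old) (NN sailor)) "
                   "(VP (VBD repaired) (NP (DT the) (NN ship))) (. .))")]
rows = [("The", "DET", "Definite=Def|PronType=Art"),
        ("old", "ADJ", "Degree=Pos"),
        ("sailor", "NOUN", "Number=Sing"),
        ("repaired", "VERB", "Tense=Past|VerbForm=Fin"),
        ("the", "DET", "Definite=Def|PronType=Art"),
        ("ship", "NOUN", "Number=Sing"),
        (".", "PUNCT", "_")]
tokens = [AnnotatedToken(form=f, pos=p, morph=m, is_punct=(p == "PUNCT"),
                         onset=0.5 * i, offset=0.5 * i + 0.4, run_id=1)
          for i, (f, p, m) in enumerate(rows)]

ncn = compute_closing_nodes(trees[0])
print("tokens:   ", [t.form for t in tokens])
print("NCN:      ", ncn, " (nodes closing at each token; sums to the tree's",
      trees[0].n_nodes(), "nodes)")

semantic = filter_content_words(tokens)
syntactic, vocab = make_syntactic_stream(tokens, ncn)
integral = make_integral_stream(tokens)
print("semantic: ", semantic.symbols, " (content words only)")
print("syntactic:", syntactic.symbols)
print(f"integral:  {integral.symbols}  ({len(vocab)} distinct triplets -> ids)")
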