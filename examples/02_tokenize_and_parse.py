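"""Tokenize a result sentence and parse it with the result grammar.

The lexer keeps only domain key words (locations, results, modifiers,
conjunctions); the chart parser derives the token stream from the grammar
and returns the parse tree whose terminal leaves are the test result.
"""

from egfrtext import default_grammar, default_lexicon, normalize, parse, tokenize

sentence = normalize("The deletions in Exon 19 was identified")
lexicon = default_lexicon()
tokens = tokenize(sentence, lexicon)
print("sentence:", sentence)
print("tokens:  ", [t.symbol for t in tokens])

tree = parse([t.symbol for t in tokens], default_grammar())
print("parse tree (variables are grammar symbols, leaves are tokens):")
print(tree.pretty())
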