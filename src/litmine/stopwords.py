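"""Frozen English stop-word list.

A fixed, versioned copy is shipped (rather than importing a live list from
another library) so that tokenization — and therefore every topic model
built on it — is reproducible across environments and library upgrades.
The list is the classic general-English function-word inventory used by
most information-retrieval systems.
"""

ENGLISH_STOPWORDS = frozenset("""
a about above after again against all am an and any are aren as at be
because been before being below between both but by can cannot could
couldn did didn do does doesn doing don down during each few for from
further had hadn has hasn have haven having he her here hers herself him
himself his how i if in into is isn it its itself just ll me mightn more
most mustn my myself needn no nor not now o of off on once only or other
our ours ourselves out over own re s same shan she should shouldn so some
such t than that the their theirs them themselves then there these they
this those through to too under until up ve very was wasn we were weren
what when where which while who whom why will with won would wouldn you
your yours yourself yourselves
""".split())
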