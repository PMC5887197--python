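# Optional real dataset

The archaeal reanalysis in `tests/test_acceptance.py` and
`scripts/acceptance.py` expects a published collection of 47 gene trees
(ribosomal proteins of 14 archaeal organisms, from the alignments of
Matte-Tailliez et al. 2002) as a multi-tree Newick file at:

    data/archaea_rproteins.nwk

The trees are publicly distributed alongside the original analysis and are
not redistributed here. Download them, concatenate the 47 Newick trees one
per line, and save under the name above; everything else is self-contained
and runs without this file.
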