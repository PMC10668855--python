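# Candidate backbone topologies for the three modern amphibian orders
# relative to amniotes, with an outgroup token. Group tokens (frog,
# salamander, caecilian, amniote, outgroup) are substituted by resolved
# clades at run time.
H1	(outgroup,(amniote,(caecilian,(frog,salamander))));
H2	(outgroup,(amniote,(frog,(salamander,caecilian))));
H3	(outgroup,(amniote,(salamander,(frog,caecilian))));
H4	(outgroup,((amniote,caecilian),(frog,salamander)));
H5	(outgroup,(frog,(amniote,(caecilian,salamander))));
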