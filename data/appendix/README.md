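# Supplementary marker tables

The published reduced marker tables (291 site-informative markers and 112
de novo informative markers, with per-individual read depths and library
sizes) are distributed with the study's supplementary material and archive
deposit, not bundled here.  To run the reproduction test, place them as:

    data/appendix/site_291/counts.tsv
    data/appendix/site_291/samples.tsv
    data/appendix/site_291/markers.tsv
    data/appendix/denovo_112/counts.tsv
    data/appendix/denovo_112/samples.tsv
    data/appendix/denovo_112/markers.tsv

using the TSV layouts described in the package README (counts: individuals
x markers; samples: individual/site/library_size; markers: marker/motif).
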