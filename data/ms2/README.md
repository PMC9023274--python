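# MS2 reference genome

The benchmark reproduction (`cpbind.datasets.ms2_summary`,
`tests/test_acceptance.py::test_ms2_benchmark_numbers` and the optional MS2
entries of `scripts/acceptance.py`) needs the 3,569-nt genome of
bacteriophage MS2, RefSeq accession **NC_001417**, which is not
redistributed with this package.

Place it here as `NC_001417.fasta`, e.g.:

    efetch -db nuccore -id NC_001417.2 -format fasta > data/ms2/NC_001417.fasta

or download the FASTA from the NCBI web record for NC_001417.

The 15 coat-protein-binding stem-loop intervals used as the reference site
set ship with the package (`cpbind.datasets.MS2_STEM_LOOPS`); only the
genome sequence itself must be supplied.
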