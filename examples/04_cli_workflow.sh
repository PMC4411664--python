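#!/usr/bin/env bash
# Shell workflow: simulate -> map -> evaluate with the splicemap CLI.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

splicemap simulate \
    --out-prefix "$workdir/demo" \
    --genome-length 100000 --genes 8 --reads 2000 \
    --mismatch-rate 0.005 --seed 7 --log-level WARNING

splicemap map \
    --ref "$workdir/demo.fa" \
    --reads "$workdir/demo.fastq" \
    --out "$workdir/demo.sam" \
    --annotation "$workdir/demo.annotation.tsv" \
    --log-level WARNING

# the SAM output is plain v1.6 text; any downstream tool can read it
samtools flagstat "$workdir/demo.sam" | head -2

splicemap evaluate \
    --sam "$workdir/demo.sam" \
    --truth "$workdir/demo.truth.tsv" | head -12
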