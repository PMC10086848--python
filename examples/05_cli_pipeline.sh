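#!/usr/bin/env bash
# File-based path: write a synthetic family to disk as word2vec text files,
# run the audit from its YAML config, and print the pooled results.
# Real audits use the same `run` step with paths to downloaded models and
# the built-in lexicons (lexicons: builtin).
set -euo pipefail

workdir=$(mktemp -d)
specbias simulate --out "$workdir/family" --seed 1
specbias run --config "$workdir/family/run.yaml" --out "$workdir/results"
specbias report --dir "$workdir/results"
rm -rf "$workdir"
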