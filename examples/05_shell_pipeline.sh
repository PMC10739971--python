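#!/bin/sh
# The same pipeline from the shell: generate data, run, inspect artifacts.
set -e
tmp=$(mktemp -d)

mda synth "$tmp/demo" --kind curve --n 80 --dim 10 --noise-sd 0.02 --seed 3
mda run "$tmp/demo_X.tsv" "$tmp/out" --targets "$tmp/demo_targets.tsv" --seed 3

echo "--- artifacts ---"
ls "$tmp/out"
echo "--- metrics ---"
cat "$tmp/out/metrics.tsv"
rm -rf "$tmp"
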