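#!/bin/sh
# End-to-end shell pipeline: synthesize a pair, register, propagate labels,
# and evaluate — the same steps a real atlas-propagation run would take with
# NIfTI files on disk.
set -e
dir=$(mktemp -d)

gcdeform synth --out-dir "$dir" --shape 24 24 24 --n-blobs 3 \
    --warp-amplitude 1.5 --warp-sigma 6 --seed 1

gcdeform register --fixed "$dir/target.nii.gz" --moving "$dir/source.nii.gz" \
    --out "$dir/field.nii.gz" --levels 2 --block-size 12 \
    --manifest "$dir/run.json" -v

gcdeform transform --input "$dir/source_labels.nii.gz" \
    --field "$dir/field.nii.gz" --out "$dir/propagated.nii.gz" --labels

echo "folding count:"
gcdeform jacobian --field "$dir/field.nii.gz"

echo "label overlap:"
gcdeform dice --a "$dir/target_labels.nii.gz" --b "$dir/propagated.nii.gz" \
    --out "$dir/dice.csv"

cat "$dir/dice.csv"
rm -r "$dir"
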