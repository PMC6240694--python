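#!/usr/bin/env bash
# The same analyses from the shell: simulate a study to TSV/GMT files,
# run the per-condition network, the consensus network, and standalone
# enrichment/hub queries on the written tables.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

coexnet simulate --seed 0 --two-conditions --out-dir "$workdir/sim"

coexnet run \
  --expression "$workdir/sim/expression.tsv" \
  --metadata "$workdir/sim/metadata.tsv" \
  --condition estrogen \
  --gene-sets "$workdir/sim/tf_targets.gmt" \
  --edges "$workdir/sim/edges.tsv" \
  --out-dir "$workdir/estrogen"

# low-dose variant of the same condition: doses strictly below 12.5 uM
coexnet run \
  --expression "$workdir/sim/expression.tsv" \
  --metadata "$workdir/sim/metadata.tsv" \
  --condition bpa --max-dose 12.5e-6 \
  --out-dir "$workdir/bpa_low_dose"

coexnet consensus \
  --expression "$workdir/sim/expression.tsv" \
  --metadata "$workdir/sim/metadata.tsv" \
  --conditions estrogen,bpa \
  --out-dir "$workdir/consensus"

coexnet report --run-dir "$workdir/estrogen" | head -n 20
echo "outputs written under $workdir (removed on exit)"
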