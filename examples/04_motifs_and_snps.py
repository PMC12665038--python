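"""Attribution-based motif recovery and SNP effect deltas.

Trains a motif-driven classifier on planted-motif pairs, attributes its
predictions back to the input bases, extracts PWMs from high-importance
windows, matches them against a motif database containing the planted
motifs plus decoys, and finally scores variants that destroy a planted
motif against variants in nearby background sequence.
"""

import numpy as np

from etnet.genomio import one_hot_encode
from etnet.interpret import attribute, attribution_to_pwms, match_motifs, snp_delta
from etnet.model import build_model, reduced_config
from etnet.synthfix import FixtureSpec, make_sequence_pairs, make_snp_system, motif_database
from etnet.traineval import train_arrays

spec = FixtureSpec()


def encode(seqs):
    return np.stack([one_hot_encode(s) for s in seqs])


# --- train a motif-driven model --------------------------------------------
val = make_sequence_pairs(100, 200, seed=8)


def stream(epoch):
    pairs = make_sequence_pairs(300, 200, seed=5000 + epoch)
    return encode(pairs.lefts), encode(pairs.rights), pairs.labels


model = build_model(reduced_config(), seed=1)
train_arrays(model, stream,
             val_data=(encode(val[0]), encode(val[1]), val[2]),
             lr=1e-3, epochs=150, batch_size=50, seed=3)

# --- attribution -> PWMs -> database match ----------------------------------
test = make_sequence_pairs(60, 200, seed=9)
positives = [i for i in range(60) if test.labels[i] == 1][:10]
tracks = [attribute(model, test.lefts[i], test.rights[i], n_references=10, seed=i)
          for i in positives]
database = motif_database(spec)  # planted motifs + random decoys
window = int(round(np.mean([m.width for m in database])))
pwms = attribution_to_pwms(tracks, window=window, quantile=0.95)
matches, counts = match_motifs(pwms, database, threshold=0.8)
print(f"{len(pwms)} high-importance windows, {len(matches)} matched at cosine >= 0.8")
print("occurrence counts:", {k: v for k, v in counts.items() if v})

# --- SNP effect deltas -------------------------------------------------------
genome, variants, partners = make_snp_system(spec, seed=5)
deltas = {"effect": [], "null": []}
for _, v in variants.iterrows():
    report = snp_delta(model, genome, (v.chrom, int(v.pos), v.ref, v.alt),
                       partners, flank=90)
    deltas[v.kind].append(report.mean_abs_delta_percent)
print(f"effect variants (motif centers):  mean |delta| = "
      f"{np.mean(deltas['effect']):.2f}%")
print(f"null variants (nearby background): mean |delta| = "
      f"{np.mean(deltas['null']):.2f}%")

# The planted motifs dominate the occurrence counts, and motif-breaking
# variants shift the predicted interaction probability far more than
# background variants in the same windows.
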