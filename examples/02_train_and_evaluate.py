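"""Train the pair classifier on planted-motif sequence pairs and evaluate.

The sequence-pair fixture plants motif A in the left and motif B in the
right sequence of every positive pair; two thirds of the negatives carry
exactly one of the motifs, so only the A-and-B co-occurrence separates the
classes. A reduced configuration trains in a few minutes on one CPU.
"""

import numpy as np

from etnet.genomio import one_hot_encode
from etnet.model import build_model, reduced_config
from etnet.synthfix import make_sequence_pairs
from etnet.traineval import metrics, train_arrays


def encode(seqs):
    return np.stack([one_hot_encode(s) for s in seqs])


val = make_sequence_pairs(100, 200, seed=8)


def stream(epoch):
    pairs = make_sequence_pairs(300, 200, seed=5000 + epoch)
    return encode(pairs.lefts), encode(pairs.rights), pairs.labels


test = make_sequence_pairs(100, 200, seed=9)

model = build_model(reduced_config(), seed=1)  # 200 bp window, 16 channels, 2 heads
history = train_arrays(model, stream,
                       val_data=(encode(val[0]), encode(val[1]), val[2]),
                       lr=1e-3, epochs=150, batch_size=50, seed=3)
print(f"best validation AUC {history.best_val_auc:.3f} at epoch {history.best_epoch}")

scores = model.predict(encode(test[0]), encode(test[1]))
report = metrics(test[2], scores)
print({k: round(v, 3) for k, v in report.to_dict().items()})

# A high held-out AUC means the network learned the planted co-occurrence
# rule: single-motif decoy negatives force it to detect both motifs, and the
# per-pair random backgrounds leave it nothing else to key on.
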