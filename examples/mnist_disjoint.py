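"""Disjoint-MNIST lifelong learning with a 400-neuron CFN.

Reproduces the real-data protocol: digits presented strictly sequentially
('0' first, '9' last, never revisiting), one epoch per digit, v_th = 13.5,
with per-stage frozen evaluation. Requires the MNIST IDX files on disk
(train-images-idx3-ubyte / train-labels-idx1-ubyte, optionally .gz) and
several hours of CPU time at this size — pass a directory containing them:

    python examples/mnist_disjoint.py /path/to/mnist
"""

import sys
from pathlib import Path

import numpy as np

from cfnet import RunConfig, Schedule, build_network, load_idx_dataset, run_schedule

if len(sys.argv) != 2:
    sys.exit(__doc__)

root = Path(sys.argv[1])


def find(stem):
    for name in (stem, stem + ".gz"):
        if (root / name).exists():
            return root / name
    sys.exit(f"missing {stem}(.gz) under {root}")


dataset = load_idx_dataset(
    find("train-images-idx3-ubyte"), find("train-labels-idx1-ubyte")
)
print(f"loaded {len(dataset.samples)} samples of dim {dataset.dim}")

cfg = RunConfig(n_neurons=400, input_dim=dataset.dim, v_th=13.5, epochs_per_task=1)
net = build_network(cfg, np.random.default_rng(0))
reports = run_schedule(net, dataset, Schedule("disjoint", 1), seed=0)
for rep in reports:
    print(f"after digit {rep.task_class}: accuracy over seen digits "
          f"= {rep.combined_accuracy:.2%}")
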