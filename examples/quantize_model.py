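"""Quantize a trained model to 32-bit integers and verify it predicts identically.

The pair table at double precision occupies 21*21*136*8 bytes per state
(468 KB); storing entries as scaled int32 halves that while perturbing each
value by at most 0.5/scale nats. The example measures how often the
per-residue argmax state differs between the float and quantized models.
"""

import os
import tempfile

import numpy as np

from gor4 import (
    default_config,
    dequantize_tables,
    generate_dataset,
    load_model,
    pair_table_bytes,
    predict_sequence,
    quantize_tables,
    save_model,
    train,
)

data = generate_dataset(default_config(seed=42))
tables = train(data)
quant = quantize_tables(tables, scale=65536.0)

print(f"per-state pair table: {pair_table_bytes(per_state=True)} bytes "
      f"({pair_table_bytes(per_state=True) // 1024} KB at float64)")
err = max(np.abs(dequantize_tables(quant).dir - tables.dir).max(),
          np.abs(dequantize_tables(quant).pairinfo - tables.pairinfo).max())
print(f"max dequantization error: {err:.3g} nats (bound {0.5 / 65536:.3g})")

with tempfile.TemporaryDirectory() as tmp:
    f_path, q_path = os.path.join(tmp, "f.gor4"), os.path.join(tmp, "q.gor4")
    save_model(tables, f_path)
    save_model(quant, q_path)
    print(f"model file: float {os.path.getsize(f_path)} bytes, "
          f"quantized {os.path.getsize(q_path)} bytes")
    quant = load_model(q_path)

agree = total = 0
for rec in data:
    s_f, _ = predict_sequence(rec.sequence, tables)
    s_q, _ = predict_sequence(rec.sequence, quant)
    agree += sum(a == b for a, b in zip(s_f.states, s_q.states))
    total += len(s_f)
print(f"argmax agreement on {total} residues: {100.0 * agree / total:.4f}%")
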