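"""Generate the synthetic study dataset.

Simulates a 20-type scaC community over the full 36-sample design
(3 animals x 3 weeks x 2 hours x 2 fractions), derives type sequences from
the scaC amplicon model, samples a ~600-clone library (17 clones per
sample), predicts per-enzyme terminal restriction fragments and renders
noisy peak tables for the scaC enzyme panel (AluI, HaeIII, MspI, RsaI).

Writes results/synthetic/: truth_abundance.csv, metadata.csv, clones.fasta,
peaks.csv, type_sequences.fasta, trf_predictions.csv, manifest.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from scatyper import digest, profiles, synthetic

K_TYPES = 20
DEPTH = 17  # clones per sample -> 612 total, matching a ~1100/2 scale survey


def main(seed: int, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    truth = synthetic.simulate_community(K_TYPES, seed=seed)
    model = synthetic.default_type_model(seed=seed)
    type_seqs = synthetic.simulate_type_sequences(model, K_TYPES, seed=seed)
    clones = synthetic.simulate_clone_library(
        truth, type_seqs, depth=DEPTH, seed=seed, model=model
    )

    truth.abundance.to_csv(outdir / "truth_abundance.csv")
    truth.design.to_csv(outdir / "metadata.csv")
    with open(outdir / "clones.fasta", "w") as fh:
        for c in clones:
            fh.write(f">{c.clone_id}\n{c.sequence}\n")
    with open(outdir / "type_sequences.fasta", "w") as fh:
        for t, s in type_seqs.items():
            fh.write(f">{t}\n{s}\n")

    fwd, rev = digest.PRIMERS["scaC"]
    tables = []
    trf_rows = []
    for enz_name in digest.ENZYME_PANELS["scaC"]:
        enz = digest.ENZYMES[enz_name]
        trfs = {}
        for t, s in type_seqs.items():
            pred = digest.predict_trf(digest.extract_amplicon(s, fwd, rev), enz, t)
            trfs[t] = pred
            trf_rows.append(
                {"type": t, "enzyme": enz_name, "forward_trf": pred.forward_trf,
                 "reverse_trf": pred.reverse_trf, "forward_uncut": pred.forward_uncut,
                 "reverse_uncut": pred.reverse_uncut}
            )
        tables.extend(synthetic.simulate_peak_tables(truth, trfs, enz_name, seed=seed))
    profiles.write_peak_tables(tables, outdir / "peaks.csv")
    pd.DataFrame(trf_rows).to_csv(outdir / "trf_predictions.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps({"k_types": K_TYPES, "depth": DEPTH, "seed": seed}, indent=2)
    )
    print(f"simulated {K_TYPES} types, {len(clones)} clones, "
          f"{len(tables)} peak tables -> {outdir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    main(args.seed, args.outdir)
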