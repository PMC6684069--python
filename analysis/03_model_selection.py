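#!/usr/bin/env python
"""Bayesian model selection over the two-segment architecture space.

Fits all 7 candidate architectures (excitatory variants) to the Welch
cross-spectra of the connected recording from step 01 and compares them
by relative Laplace log evidence and posterior probability; then
summarizes the winning architecture's symmetry-averaged coupling
strengths with the max-to-1 normalization.

Writes results/bms_two_segment.json and results/strengths.json.
"""

import argparse
import json
from pathlib import Path

from cpgnet.architectures import two_segment_architecture
from cpgnet.bms import bms, summarize_strengths
from cpgnet.csd import empirical_csd
from cpgnet.fitting import fit_model
from cpgnet.preprocess import preprocess
from cpgnet.recording import read_recording


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--starts", type=int, default=4)
    args = ap.parse_args()

    prep = preprocess(read_recording(args.datadir / "connected.tsv"))
    S = empirical_csd(prep)
    fits = []
    for arch_id in range(1, 8):
        arch = two_segment_architecture(arch_id)
        fit = fit_model(S, arch, n_starts=args.starts, seed=args.seed)
        fits.append(fit)
        print(f"{arch.id}: {arch.n_connections:2d} connections, "
              f"log evidence {fit.log_evidence:.1f}")

    res = bms(fits)
    print("\nrelative log evidence (vs least probable) and posterior probability:")
    for m, rel, p in zip(res.model_ids, res.relative_log_evidence, res.posterior_prob):
        print(f"  {m}: {rel:8.1f}   {p:.4f}")
    print(f"winner: {res.winner}")
    rel = dict(zip(res.model_ids, res.relative_log_evidence))
    gap_sparse = min(rel[res.winner] - rel[m] for m in ("2seg-5", "2seg-6", "2seg-7"))
    print(
        f"\nmodels without full inter+intra coupling trail by >= {gap_sparse:.0f} nats; "
        "the recording is globally phase-locked, so the members of the\n"
        "connected-model cluster (1-4) are separated by far less than that -- "
        "architecture identity inside the cluster is weakly determined here."
    )

    winner_fit = [f for f in fits if f.architecture.id == res.winner]
    summary = summarize_strengths(winner_fit, normalization="max_to_1")
    print("\nnormalized strengths (max -> 1):")
    for cls, v in summary.class_means.items():
        print(f"  {cls}: {v:.3f}")

    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "bms_two_segment.json").write_text(json.dumps(res.to_dict(), indent=1))
    (args.outdir / "strengths.json").write_text(json.dumps(summary.to_dict(), indent=1))
    print(f"\nwrote {args.outdir / 'bms_two_segment.json'}")


if __name__ == "__main__":
    main()
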