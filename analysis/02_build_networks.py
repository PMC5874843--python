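#!/usr/bin/env python
"""Construct the crosslinked hydrogel series at four cyclodextrin loadings.

Builds scaled-down analogues of the four reference formulations (0, 6, 12,
24 grafted cyclodextrins scale here to 0-3), records their composition
summaries, and writes one PDB per model under results/network/.  Pass
``--full`` to build the full-scale 56-chain matrix instead (several
minutes).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gelforge.io import write_pdb
from gelforge.network import BuilderConfig, build_hydrogel
from gelforge.structures import Molecule
from gelforge.synthetic import make_guest_stub

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "network"

SCALED = dict(n_chains=9, chain_length=10, box_lengths=(32.0, 32.0, 34.0),
              pva_sa_ratio=(10, 2), relax_steps=5, n_guests=5,
              guest_min_distance=8.0)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--full", action="store_true",
                        help="full-scale 56-chain build (slow)")
    parser.add_argument("--write-pdb", action="store_true",
                        help="also export one PDB per model")
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    guest, _ = make_guest_stub(SEED)
    rows = []
    cd_series = [0, 1, 2, 3] if not args.full else [0, 6, 12, 24]
    for n_cd in cd_series:
        cfg = (BuilderConfig(n_cd=n_cd, seed=SEED)
               if args.full else
               BuilderConfig(**SCALED, n_cd=n_cd, seed=SEED))
        model = build_hydrogel(cfg, guest=guest)
        comp = model.composition()
        comp["n_cd_requested"] = n_cd
        rows.append(comp)
        print(f"n_cd={n_cd}: {comp['crosslink_count']} bridges, "
              f"CD mass fraction {comp['cd_mass_fraction']:.3f}, "
              f"{comp['guest_count']} guests placed")
        if args.write_pdb:
            mols = model.gel_molecules() + model.guests
            elements, coords, chain_idx, het = [], [], [], []
            for mi, m in enumerate(mols):
                elements += m.elements
                coords.append(m.positions)
                chain_idx += [mi] * len(m)
                het += [mi >= len(model.chains)] * len(m)
            write_pdb(Molecule(elements, np.vstack(coords)),
                      OUT / f"hydrogel_cd{n_cd}.pdb",
                      chain_indices=chain_idx, het_mask=het)
    pd.DataFrame(rows).to_csv(OUT / "compositions.csv", index=False,
                              float_format="%.6g")
    (OUT / "build_config.json").write_text(json.dumps(
        {"scaled": SCALED, "seed": SEED, "full": args.full}, indent=2,
        default=str) + "\n")
    print(f"wrote {len(rows)} models to {OUT}")


if __name__ == "__main__":
    main()
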