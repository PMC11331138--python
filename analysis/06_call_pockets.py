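"""Filter predicted complexes by ipTM and call consensus binding pockets.

Parses the toy model ensemble with its confidence sidecar, keeps the
confident models (ipTM > 0.84, AFM scheme), extracts contacts and
hydrogen bonds, calls per-position pockets and forms the cross-model
consensus for the motif positions 5 and 7.  Also superposes all
confident models onto the first one.  Writes results/contacts.tsv and
results/consensus_pockets.json.
"""

import argparse
import json
import pathlib

import pandas as pd

from lrrpockets.structures import (
    consensus_pockets,
    filter_models,
    hydrogen_bonds,
    parse_structure,
    read_sidecar,
    superpose_models,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]
ROLES = {"A": "receptor", "B": "peptide"}


def main(simdir: pathlib.Path, outdir: pathlib.Path,
         scheme: str = "afm", min_support: float = 0.5,
         modelsdir: pathlib.Path | None = None) -> None:
    mdir = modelsdir or ROOT / "scratch" / "models"
    sidecar = read_sidecar(mdir / "confidence.json")
    models = [
        parse_structure(p, ROLES, sidecar=sidecar, model_id=p.stem)
        for p in sorted(mdir.glob("*.pdb"))
    ]
    confident, gray, rejected = filter_models(models, scheme)

    contact_rows = []
    per_model = []
    for m in confident:
        contacts = hydrogen_bonds(m)
        per_model.append(contacts)
        for c in contacts:
            contact_rows.append(
                (m.model_id, c.receptor_residue[1], c.peptide_position,
                 round(c.distance, 2), c.hbond)
            )
    call = consensus_pockets(per_model, min_support=min_support)
    rmsds = [superpose_models(confident[0], m)[2] for m in confident[1:]]

    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        contact_rows,
        columns=["model", "receptor_residue", "peptide_position",
                 "min_distance_A", "hbond"],
    ).to_csv(outdir / "contacts.tsv", sep="\t", index=False)
    payload = {
        "scheme": scheme,
        "n_confident": len(confident),
        "n_gray": len(gray),
        "n_rejected": len(rejected),
        "min_support": min_support,
        "pockets": {str(p): sorted(v) for p, v in call.pockets.items()},
        "support": {f"{p}:{r}": n
                    for (p, r), n in sorted(call.support.items())},
        "max_pairwise_rmsd_A": round(max(rmsds), 3) if rmsds else None,
    }
    (outdir / "consensus_pockets.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True))

    print(f"{len(models)} models: {len(confident)} confident / "
          f"{len(gray)} gray / {len(rejected)} rejected ({scheme}); "
          f"consensus pockets {payload['pockets']}; "
          f"max CA rmsd to model 1: {payload['max_pairwise_rmsd_A']} A")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=pathlib.Path,
                    default=ROOT / "results" / "simulated")
    ap.add_argument("--outdir", type=pathlib.Path,
                    default=ROOT / "results")
    ap.add_argument("--scheme", choices=["afm", "af3"], default="afm")
    ap.add_argument("--min-support", type=float, default=0.5)
    args = ap.parse_args()
    main(args.simdir, args.outdir, args.scheme, args.min_support)
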