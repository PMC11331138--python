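"""Generate the synthetic study inputs for the whole pipeline.

Emits, under results/simulated/: the aligned receptor family (FASTA), the
precursor set (FASTA), per-species gene tables (TSV), the toy complex
ensemble (PDB + ipTM sidecar JSON) and the ground-truth record of what
was planted — so every later stage can be checked against truth.
"""

import argparse
import json
import pathlib

from lrrpockets.simulate import (
    SimConfig,
    generate_complex_ensemble,
    generate_gene_tables,
    generate_precursor_set,
    generate_receptor_family,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main(seed: int, outdir: pathlib.Path) -> None:
    cfg = SimConfig(seed=seed)
    outdir.mkdir(parents=True, exist_ok=True)

    fam = generate_receptor_family(cfg)
    (outdir / "receptor_family.fasta").write_text(fam.fasta())
    (outdir / "receptor_truth.json").write_text(fam.truth.to_json())

    pre = generate_precursor_set(cfg)
    (outdir / "precursors.fasta").write_text(pre.fasta())
    (outdir / "precursor_truth.json").write_text(pre.truth.to_json())

    tables = generate_gene_tables(cfg)
    gdir = outdir / "gene_tables"
    gdir.mkdir(exist_ok=True)
    for sp in tables.tables:
        (gdir / f"{sp}.tsv").write_text(tables.tsv(sp))
    (outdir / "locus_proteins.json").write_text(
        json.dumps(tables.proteins, sort_keys=True, indent=1))
    (outdir / "locus_truth.json").write_text(tables.truth.to_json())

    ens = generate_complex_ensemble(cfg)
    # structure models are bulky regenerable artifacts: keep them under
    # scratch/, outside the curated results tree
    mdir = ROOT / "scratch" / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    for mid, pdb, _ in ens.models:
        (mdir / f"{mid}.pdb").write_text(pdb)
    (mdir / "confidence.json").write_text(ens.sidecar_json())
    (outdir / "complex_truth.json").write_text(ens.truth.to_json())

    print(f"seed {seed}: wrote {cfg.n_species} receptor homologues, "
          f"{len(pre.records)} precursor records "
          f"({cfg.n_clusters} families + {cfg.n_decoys} decoys), "
          f"{len(tables.tables)} gene tables -> {outdir}; "
          f"{len(ens.models)} complex models -> {mdir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=pathlib.Path,
                    default=ROOT / "results" / "simulated")
    args = ap.parse_args()
    main(args.seed, args.outdir)
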