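#!/usr/bin/env python
"""Optional regression against deposited structures (requires network + edits).

This script is NOT part of the default test suite: it downloads coordinate
files from the PDB and therefore only runs on a machine with network access.
It exercises the pipeline on the deposited phycobilisome core (7VEA) and
phycocyanin rod (7VEB), and the crystallographic rod packing derived from
3O2C:

  1. chromophore census of the core (expected: 84 phycocyanobilins);
  2. the short inter-chromophore distances of the core network, including
     the ~20 Å ApcF–alpha-LCM terminal-emitter pair;
  3. anchored per-monomer RMSD of the cryo-EM rod against the crystal rod
     (Disk A ~0.5–4 Å; Disk B tens of Å), anchored on rod monomer 1;
  4. the ~1.3 Å CpcC(234–287)-vs-CpcD region RMSD.

Before running, the placeholder chain IDs in
``src/pbsfret/configs/core_inventory_synthetic.cfg`` must be replaced by the
deposition's own chain IDs (from its struct_asym/entity annotations), and a
rod assembly map written for 7VEB. The 3O2C crystal rod must be supplied as
pre-assembled coordinates (apply the entry's assembly records with, e.g.,
``gemmi convert --assembly``); generating it is documented here, not coded.

Usage:
    python scripts/regression_deposited.py --workdir scratch/deposited \
        --core-map <edited core map> --rod-map <rod map> \
        --crystal-rod <assembled 3O2C rod.cif> --crystal-map <crystal rod map>
"""

from __future__ import annotations

import argparse
import subprocess
import sys
from pathlib import Path

from pbsfret import (
    all_pairs,
    anchored_rmsd,
    bridging_pairs,
    build_graph,
    default_sinks,
    extract_chromophores,
    load_assembly_map,
    pair_units,
    read_structure,
    region_rmsd,
    units_from_map,
)


def fetch(pdb_id: str, workdir: Path) -> Path:
    dest = workdir / f"{pdb_id.lower()}.cif"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
        subprocess.run(["curl", "-sSfL", "-o", str(dest), url], check=True)
    return dest


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("scratch/deposited"))
    ap.add_argument("--core-map", type=Path, required=True)
    ap.add_argument("--rod-map", type=Path, required=True)
    ap.add_argument("--crystal-rod", type=Path, required=True)
    ap.add_argument("--crystal-map", type=Path, required=True)
    ap.add_argument("--cutoff", type=float, default=35.0)
    args = ap.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    # 1-2: core census + network
    core = read_structure(fetch("7VEA", args.workdir))
    core_map = load_assembly_map(args.core_map)
    chroms = extract_chromophores(core, core_map)
    print(f"core chromophores: {len(chroms)} (expected 84)")
    pairs = all_pairs(chroms, cutoff=args.cutoff)
    graph = build_graph(pairs, default_sinks([c.id for c in chroms]))
    print("bridging pairs (ascending r):")
    for p in bridging_pairs(graph, core_map):
        print(f"  {p.donor_id} -- {p.acceptor_id}  r={p.r:.1f} A  kappa2={p.kappa_sq:.2f}")

    # 3: anchored rod comparison
    rod = units_from_map(read_structure(fetch("7VEB", args.workdir)), load_assembly_map(args.rod_map))
    crystal = units_from_map(read_structure(args.crystal_rod), load_assembly_map(args.crystal_map))
    shared = sorted(set(rod) & set(crystal), key=lambda u: (len(u), u))
    pairings = [pair_units(rod[u], crystal[u], u, u) for u in shared]
    res = anchored_rmsd({u: rod[u] for u in shared}, {u: crystal[u] for u in shared}, "1", pairings)
    print(res.report())

    # 4: CpcC "CpcD-like" region vs CpcD
    rod_model = read_structure(args.workdir / "7veb.cif")
    rod_map = load_assembly_map(args.rod_map)
    cpcc = [c for c, a in rod_map.chain_assignments.items() if a.subunit_role == "CpcC"]
    cpcd = [c for c, a in rod_map.chain_assignments.items() if a.subunit_role == "CpcD"]
    if cpcc and cpcd:
        r = region_rmsd(
            rod_model.chain(cpcc[0]), (234, 287),
            rod_model.chain(cpcd[0]), (1, 10_000),
        )
        print(f"CpcC(234-287) vs CpcD region RMSD: {r:.2f} A (expected ~1.3)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
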