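#!/usr/bin/env python
"""Edge-to-edge chromophore–residue distances.

Computes minimum heavy-atom distances between the FMN isoalloxazine ring and
aromatic side chains on a synthetic miniature structure bundled with the
analysis (a real LOV-domain PDB file, e.g. 4EES, can be substituted via
--pdb to reproduce published distances). Writes results/distances.json.
"""

import argparse
import json
import sys
from pathlib import Path

from lovspec.structure import default_selection, edge_to_edge, parse_structure

ROOT = Path(__file__).resolve().parent.parent / "results"

# synthetic miniature structure: an FMN ring fragment flanked by one Tyr and
# one Trp ring fragment at known separations (not a crystal structure)
SYNTHETIC_PDB = """\
HETATM    1  N5  FMN A 501      10.000  10.000  10.000  1.00  0.00           N
HETATM    2  C4A FMN A 501      11.400  10.000  10.000  1.00  0.00           C
HETATM    3  C8  FMN A 501      13.000  11.500  10.000  1.00  0.00           C
ATOM      4  CZ  TYR A  59       5.000  10.000  10.000  1.00  0.00           C
ATOM      5  OH  TYR A  59       3.600  10.000  10.000  1.00  0.00           O
ATOM      6  CZ2 TRP A  67      10.000  21.000  10.000  1.00  0.00           C
ATOM      7  CH2 TRP A  67      10.000  22.400  10.000  1.00  0.00           C
END
"""


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb", type=Path, default=None,
                        help="Optional real PDB file to analyse instead.")
    args = parser.parse_args()

    ROOT.mkdir(parents=True, exist_ok=True)
    if args.pdb is None:
        pdb_path = ROOT / "synthetic_mini.pdb"
        pdb_path.write_text(SYNTHETIC_PDB)
        print(f"using bundled synthetic miniature structure ({pdb_path})")
    else:
        pdb_path = args.pdb

    atoms = parse_structure(pdb_path)
    fmn = default_selection("FMN")
    out = {}
    for resname, resnum in [("TYR", 59), ("TRP", 67)]:
        try:
            result = edge_to_edge(
                fmn, default_selection(resname, resnum), atoms
            )
        except Exception:
            continue
        print(f"FMN ↔ {resname}{resnum}: {result.distance:.2f} Å "
              f"({result.atom_a} – {result.atom_b})")
        out[f"{resname}{resnum}"] = {
            "distance_A": result.distance,
            "atom_pair": [result.atom_a, result.atom_b],
        }

    (ROOT / "distances.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {ROOT / 'distances.json'}")


if __name__ == "__main__":
    sys.exit(main())
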