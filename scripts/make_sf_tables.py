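"""Regenerate the bundled atomic scattering-factor tables.

Writes one ``.nff``-layout text file per element (columns: photon energy
in eV, f1, f2) into ``src/fxisim/data/nff/``.  Values are computed with
the Cromer-Liberman algorithm as implemented in gemmi; f1 includes the
number of electrons Z (forward-scattering convention), f2 is the
absorptive part.

Run from the repository root:

    python scripts/make_sf_tables.py
"""

from pathlib import Path

import gemmi
import numpy as np

ELEMENTS = ["H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "K", "Ca", "Mn", "Fe", "Zn", "Se"]

E_MIN = 100.0     # eV
E_MAX = 30000.0   # eV
N_SAMPLES = 160

OUT = Path(__file__).resolve().parents[1] / "src" / "fxisim" / "data" / "nff"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    energies = np.geomspace(E_MIN, E_MAX, N_SAMPLES)
    for symbol in ELEMENTS:
        z = gemmi.Element(symbol).atomic_number
        lines = [f"# {symbol}  Z={z}  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')\n"]
        for e in energies:
            fp, fpp = gemmi.cromer_liberman(z=z, energy=float(e))
            f1 = z + fp
            f2 = max(fpp, 0.0)
            lines.append(f"{e:.6e}\t{f1:.6e}\t{f2:.6e}\n")
        path = OUT / f"{symbol.lower()}.nff"
        path.write_text("".join(lines))
        print(f"wrote {path} ({path.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
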