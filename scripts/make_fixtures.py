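#!/usr/bin/env python
"""Regenerate the shipped fixture datasets under fixtures/.

Both are fully determined by their generator configs and seeds; this
script exists so the text fixtures can be reproduced byte-for-byte.
"""

from dataclasses import replace
from pathlib import Path

from nirpls import default_config, simulate_dataset
from nirpls.data_model import write_references, write_spectra

OUT = Path(__file__).resolve().parent.parent / "fixtures"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    small = replace(default_config(seed=42), n_per_phase=(8, 6, 6))
    dataset, refs = simulate_dataset(small)
    write_spectra(dataset, OUT / "small20_spectra.csv")
    write_references(refs, OUT / "small20_references.csv")

    full = default_config(seed=1)
    dataset, refs = simulate_dataset(full)
    write_spectra(dataset, OUT / "full93_spectra.csv")
    write_references(refs, OUT / "full93_references.csv")
    print(f"fixtures written to {OUT}")


if __name__ == "__main__":
    main()
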