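"""Regenerate the packaged default parameter table from the design bootstrap.

Run from the repository root:  python scripts/make_fixture.py
"""

from pathlib import Path

from methanomod.io import write_parameter_tsv
from methanomod.synthetic import fixture_barkeri

out = Path(__file__).resolve().parents[1] / "src" / "methanomod" / "data" \
    / "barkeri_params.tsv"
out.parent.mkdir(parents=True, exist_ok=True)
write_parameter_tsv(fixture_barkeri(), out)
print(f"wrote {out}")
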