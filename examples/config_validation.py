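"""Config round trip and the error-checking behaviour.

Builds a valid two-electrode configuration, saves and reloads it, then
shows how an invalid document is rejected with a COMPLETE list of
violations (not just the first one found).
"""

import tempfile
from pathlib import Path

from porefield import ConfigError, default_config_dict, load_config, save_config, validate_config

raw = default_config_dict("pair")
cfg = validate_config(raw)
print(f"valid config: {len(cfg.layout.electrodes)} electrodes, "
      f"{cfg.thresholds.e_rev:.0f}/{cfg.thresholds.e_irrev:.0f} {cfg.thresholds.unit} thresholds")

with tempfile.TemporaryDirectory() as d:
    p = Path(d) / "cfg.json"
    save_config(cfg, p)
    assert load_config(p).layout == cfg.layout
    print(f"round trip through {p.name}: OK")

bad = dict(raw, electrode_diameter_mm=0.01, tissue_area_mm2=1e6)
bad["thresholds"] = {"e_rev": 900.0, "e_irrev": 800.0}
try:
    validate_config(bad)
except ConfigError as exc:
    print(f"\ninvalid config rejected with {len(exc.errors)} violations:")
    for e in exc.errors:
        print(f"  - {e}")
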