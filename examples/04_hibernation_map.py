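"""Map the potential hibernation area on a synthetic latitudinal gradient.

Writes a small gridded daily-temperature NetCDF (warm south, cold north),
classifies every cell for one winter, and summarises the suitable band.
"""

import tempfile
from pathlib import Path

import hiberniche as hn

sm = hn.reference_state_model()
tc = hn.reference_thermo_curves()

grid = hn.GridSpec(40.0, 50.0, 10.0, 11.0, resolution=0.5)  # 20 x 2 cells
cfg = hn.ClimateSimConfig(annual_mean=19.0, amplitude=11.0, noise_sd=0.0,
                          years=range(2015, 2016))
path = Path(tempfile.mkdtemp()) / "gradient.nc"
hn.simulate_grid_climate(grid, lat_gradient=-2.2, base_config=cfg, path=path)

tas = hn.read_daily_tas(path, grid, winter_year=2015)
smap = hn.map_suitability(tas, sm, tc)

symbols = {"no_season": ".", "suitable": "S", "unsuitable": "X"}
print("lat   class (south -> north)")
for i, lat in enumerate(smap.lats):
    fat = smap.fat_consumed[i, 0]
    fat_txt = f"{fat:6.1f} g" if fat == fat else "   (no season)"
    print(f"{lat:5.2f}  {symbols[smap.classes[i, 0]]}  {fat_txt}")

summary = hn.area_summary(smap)
print(f"potential hibernation area: {summary.area_km2:,.0f} km², "
      f"median latitude {summary.median_lat:.2f} °N "
      f"(range {summary.min_lat:.2f}-{summary.max_lat:.2f})")
# South of the band winters are too warm to force hibernation; north of it
# the season is so long and cold that 27 g of fat is not enough.
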