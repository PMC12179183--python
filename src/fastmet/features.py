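"""Catalogue of the environmental covariates used for envirotyping.

Thirty-seven features spanning geography, climate (NASA-POWER-style daily
summaries aggregated over the growing season) and soil (SoilGrids-style
profile attributes).  Each entry records the plausible range observed in
South-Eastern African soybean trial environments; the synthetic covariate
generator uses these ranges to keep simulated tables on realistic scales.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureInfo:
    """One environmental covariate: identifier, group, unit and range."""

    id: str
    name: str
    group: str
    unit: str
    min: float
    mean: float
    max: float

    @property
    def scale(self) -> float:
        """Rough per-feature SD: one sixth of the observed range."""
        return (self.max - self.min) / 6.0


#: canonical covariate dictionary (geographic, climatic, soil)
FEATURE_CATALOGUE: tuple[FeatureInfo, ...] = (
    FeatureInfo("alt", "Altitude", "geographic", "m", 70.0, 1039.0, 1359.0),
    FeatureInfo("tmean", "Mean temperature", "climatic", "degC", 17.57, 21.90, 26.29),
    FeatureInfo("tmax", "Maximum temperature", "climatic", "degC", 24.23, 27.11, 31.27),
    FeatureInfo("tmin", "Minimum temperature", "climatic", "degC", 11.59, 17.60, 23.68),
    FeatureInfo("prec", "Precipitation", "climatic", "mm/day", 0.02, 5.66, 11.63),
    FeatureInfo("wsm", "Wind speed", "climatic", "m/s", 1.60, 2.27, 4.07),
    FeatureInfo("rhm", "Relative humidity", "climatic", "%", 49.96, 77.31, 88.06),
    FeatureInfo("tmdew", "Dew point temperature", "climatic", "degC", 9.19, 17.13, 21.43),
    FeatureInfo("lw", "Longwave radiation", "climatic", "MJ/m2/day", 28.96, 32.41, 35.77),
    FeatureInfo("sw", "Shortwave radiation", "climatic", "MJ/m2/day", 16.79, 20.08, 22.89),
    FeatureInfo("gdd", "Growing degree days", "climatic", "degC/day", 10.33, 14.36, 18.38),
    FeatureInfo("fue", "Radiation use efficiency", "climatic", "-", 0.47, 0.65, 0.84),
    FeatureInfo("tmrange", "Temperature range", "climatic", "degC", 4.67, 9.52, 13.94),
    FeatureInfo("vpd", "Vapor pressure deficit", "climatic", "kPa", 0.43, 0.84, 1.81),
    FeatureInfo("spv", "Slope of vapor pressure curve", "climatic", "kPa/degC", 0.13, 0.17, 0.20),
    FeatureInfo("etp", "Potential evapotranspiration", "climatic", "mm/day", 7.63, 9.02, 10.38),
    FeatureInfo("petp", "Precipitation deficit", "climatic", "mm/day", -9.29, -3.36, 3.19),
    FeatureInfo("totprec", "Total precipitation", "climatic", "mm", 2.69, 772.73, 1451.87),
    FeatureInfo("aveprec", "Average precipitation", "climatic", "mm/day", 0.02, 5.66, 11.63),
    FeatureInfo("etptol", "Evapotranspiration tolerance", "climatic", "mm", 847.0, 1300.0, 2185.0),
    FeatureInfo("watbal", "Water balance", "climatic", "mm", -1802.7, -526.8, 376.2),
    FeatureInfo("bdod", "Bulk density of fine earth", "soil", "kg/m3", 120.0, 142.6, 155.0),
    FeatureInfo("cec", "Cation exchange capacity", "soil", "cmol/kg", 60.0, 89.28, 142.0),
    FeatureInfo("cfvo", "Coarse fragments volume", "soil", "%", 2.0, 23.62, 67.0),
    FeatureInfo("clay", "Clay content", "soil", "%", 105.0, 205.4, 436.0),
    FeatureInfo("nit", "Nitrogen content", "soil", "g/kg", 84.0, 118.0, 170.0),
    FeatureInfo("ocd", "Organic carbon density", "soil", "kg/m3", 165.0, 210.9, 257.0),
    FeatureInfo("phh2o", "Soil pH (H2O)", "soil", "-", 54.0, 61.19, 64.0),
    FeatureInfo("sand", "Sand content", "soil", "%", 336.0, 653.1, 811.0),
    FeatureInfo("silt", "Silt content", "soil", "%", 63.0, 141.5, 257.0),
    FeatureInfo("soc", "Soil organic carbon", "soil", "g/kg", 115.0, 153.7, 206.0),
    FeatureInfo("wv0010", "Soil water content at 10 kPa", "soil", "-", 249.0, 308.3, 383.0),
    FeatureInfo("wv0033", "Soil water content at 33 kPa", "soil", "-", 184.0, 230.9, 331.0),
    FeatureInfo("wv1500", "Soil water content at 1500 kPa", "soil", "-", 68.0, 104.2, 199.0),
    FeatureInfo("tsoil", "Soil temperature", "soil", "degC", 226.17, 253.46, 292.83),
    FeatureInfo("sts", "Temperature seasonality", "soil", "degC", 86.1, 155.2, 255.7),
    FeatureInfo("iso", "Isothermality", "soil", "-", -84.6, 13.67, 30.7),
    FeatureInfo("mdr", "Mean diurnal range", "soil", "-", -2.0, 1.17, 2.4),
)

FEATURE_IDS: tuple[str, ...] = tuple(f.id for f in FEATURE_CATALOGUE)
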