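# tsradiomics feature-panel manifest, version 1.
# 60 features: 19 whole-ROI histogram + 9 outer + 9 delta + 10 shape + 11 GLCM + 2 ISZ.
# Category order fixes the column order of every feature table.
version: 1
categories:
  histogram:
    - mean
    - median
    - minimum
    - maximum
    - range
    - sd
    - variance
    - skewness
    - kurtosis
    - energy
    - entropy
    - rms
    - iqr
    - mad
    - upp
    - p2_5
    - p25
    - p75
    - p97_5
  outer:
    - mean_outer
    - median_outer
    - sd_outer
    - minimum_outer
    - maximum_outer
    - skewness_outer
    - kurtosis_outer
    - energy_outer
    - entropy_outer
  delta:
    - mean_delta
    - median_delta
    - sd_delta
    - minimum_delta
    - maximum_delta
    - skewness_delta
    - kurtosis_delta
    - energy_delta
    - entropy_delta
  shape:
    - volume
    - surface_area
    - surface_to_volume_ratio
    - compactness
    - sphericity
    - convexity
    - max_3d_diameter
    - elongation
    - density
    - mass
  glcm:
    - glcm_autocorrelation
    - glcm_contrast
    - glcm_correlation
    - glcm_dissimilarity
    - glcm_energy
    - glcm_entropy
    - glcm_homogeneity
    - glcm_cluster_shade
    - glcm_cluster_prominence
    - glcm_sum_average
    - glcm_variance
  isz:
    - intensity_variability
    - size_zone_variability
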