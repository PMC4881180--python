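region_kind,variable,label,p25,p50,p75,estimate,ci_low,ci_high,cum_adj_r2,scaling,percentiles_ambiguous
urban,sqrt(vehicles_100) * season,Sqrt vehicles in 100 m buffer x season,172,8369,66117,-0.219,-0.265,-0.172,0.291,iqr,True
urban,log(dispersion_no2),Log NO2 from dispersion model (log ug/m3),3.21,3.28,3.37,0.052,0.039,0.065,0.341,iqr,False
urban,log(aqm_no2),Log NO2 from rural background AQM station (log ug/m3),2.3,2.68,3.03,0.216,0.181,0.252,0.372,iqr,False
urban,sqrt(vehicles_100),Sqrt vehicles in 100 m buffer (sqrt N),139,1199,73074,0.404,0.362,0.446,0.437,iqr,True
urban,log(inv_dist_major_road),Log 1/distance to the nearest major road (log 1/m),-4.08,-2.95,-2.61,0.163,0.144,0.181,0.470,iqr,False
urban,year,Linear time trend (year),2002.6,2005.2,2007.7,0.477,0.387,0.567,0.488,iqr,False
urban,season,"Season (summer=1, mid-season=2, winter=3)",1,2,3,0.191,0.118,0.264,0.499,iqr,False
urban,lu_industrial_300,Industrial land use in 300 m buffer (fraction),0,0,0.237,0.436,0.384,0.487,0.506,per_0_to_100,False
urban,pop_100,Population in 100 m buffer (N),0.95,141,323,0.118,0.097,0.139,0.514,iqr,False
urban,square(road_major_len_100),Squared total length of major roads in 100 m buffer (m^2),26931,48969,147510,0.296,0.259,0.334,0.519,iqr,False
urban,road_major_len_100,Total length of major roads in 100 m buffer (m),164,221,384,-0.414,-0.472,-0.356,0.534,iqr,False
urban,square(year),Linear time trend squared (year^2),4010406.76,4020827.04,4030859.29,-0.462,-0.563,-0.36,0.540,iqr,False
urban,temperature,Temperature (Celsius),3.4,9.05,15.59,-0.081,-0.126,-0.035,0.540,iqr,False
urban,square(boundary_layer_height),Squared boundary layer height (m^2),16723,79082,359729,-0.013,-0.024,-0.002,0.541,iqr,False
urban,road_major_len_100 * temperature,Total length of major roads in 100 m buffer x temperature,0,1485,3807,0.034,0.0,0.069,0.541,iqr,False
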