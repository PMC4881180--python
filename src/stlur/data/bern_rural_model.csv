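region_kind,variable,label,p25,p50,p75,estimate,ci_low,ci_high,cum_adj_r2,scaling,percentiles_ambiguous
rural,road_major_len_100 * season,Total length of major roads in 100 m buffer x season,0,294,563,-0.363,-0.382,-0.345,0.278,iqr,False
rural,vehicles_50,Vehicles in 50 m buffer (N),670,8862,17305,0.146,0.141,0.150,0.334,iqr,True
rural,lu_highdens_200,High density residential land use in 200 m buffer (fraction),0,0,0,0.410,0.389,0.430,0.372,per_0_to_100,False
rural,log(aqm_no2),Log NO2 from rural background AQM station (log ug/m3),2.28,2.62,2.98,0.250,0.239,0.262,0.406,iqr,False
rural,log(dispersion_no2),Log NO2 from dispersion model (log ug/m3),2.94,3.08,3.21,0.028,0.022,0.035,0.510,iqr,False
rural,road_major_len_100,Total length of major roads in 100 m buffer (m),0,197,238,0.474,0.456,0.492,0.563,iqr,False
rural,season,"Season (summer=1, mid-season=2, winter=3)",1,2,3,0.181,0.158,0.203,0.578,iqr,False
rural,sqrt(traffic_nearest_road),Sqrt traffic on the nearest road (sqrt N),0.0,12.5,67.3,0.098,0.092,0.104,0.591,iqr,False
rural,lu_industrial_300,Industrial land use in 300 m buffer (fraction),0,0,0,0.321,0.300,0.342,0.603,per_0_to_100,False
rural,pop_100,Population in 100 m buffer (N),13.5,103.3,156.1,0.051,0.045,0.057,0.611,iqr,False
rural,year,Linear time trend (year),2001.7,2004.3,2007.1,0.529,0.499,0.558,0.614,iqr,False
rural,square(year),Linear time trend squared (year^2),4006802.89,4017218.49,4028450.41,-0.559,-0.593,-0.525,0.618,iqr,False
rural,road_major_len_1000,Total length of major roads in 1000 m buffer (m),0,197,238,0.038,0.030,0.046,0.622,iqr,False
rural,temperature,Temperature (Celsius),3.65,9.75,16.14,-0.102,-0.115,-0.090,0.625,iqr,False
rural,altitude,Altitude (m),460,535,561,-0.032,-0.036,-0.028,0.628,iqr,False
rural,lu_lowdens_200,Low density residential land use in 200 m buffer (fraction),0.301,0.999,0.999,0.108,0.094,0.122,0.631,per_0_to_100,False
rural,boundary_layer_height,Boundary layer height (m),126.2,319.7,656.2,-0.022,-0.030,-0.014,0.632,iqr,False
rural,road_major_len_500,Total length of major roads in 500 m buffer (m),0,197,238,0.012,0.004,0.020,0.632,iqr,False
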