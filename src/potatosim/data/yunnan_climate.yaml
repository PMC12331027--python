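# Monthly climate recorded by the on-site weather stations at the three
# Yunnan trial locations (2013-2015 cropping seasons).
# Units: tmax/tmin degC (monthly mean daily extremes); rain mm (monthly
# total); sr MJ m-2 d-1 (monthly mean daily solar radiation); snh h
# (monthly mean daily sunshine hours).
spring:
  - {month: Mar, tmax: 19.5, tmin: 10.5, rain: 14.2, sr: 19.8, snh: 11.8}
  - {month: Apr, tmax: 21.8, tmin: 11.8, rain: 21.4, sr: 20.5, snh: 12.6}
  - {month: May, tmax: 21.3, tmin: 10.2, rain: 128.0, sr: 19.8, snh: 13.3}
  - {month: Jun, tmax: 19.6, tmin: 12.6, rain: 236.2, sr: 13.3, snh: 13.6}
  - {month: Jul, tmax: 20.3, tmin: 12.3, rain: 354.4, sr: 14.3, snh: 13.4}
  - {month: Aug, tmax: 19.4, tmin: 12.1, rain: 150.2, sr: 15.2, snh: 12.9}
  - {month: Sep, tmax: 20.1, tmin: 11.3, rain: 244.8, sr: 17.5, snh: 12.1}
autumn:
  - {month: Aug, tmax: 23.9, tmin: 16.1, rain: 180.4, sr: 12.7, snh: 12.2}
  - {month: Sep, tmax: 24.1, tmin: 16.3, rain: 41.4, sr: 11.1, snh: 12.1}
  - {month: Oct, tmax: 20.9, tmin: 11.4, rain: 89.4, sr: 12.9, snh: 11.4}
  - {month: Nov, tmax: 19.22, tmin: 8.6, rain: 15.8, sr: 13.1, snh: 10.8}
  - {month: Dec, tmax: 13.7, tmin: 5.1, rain: 35.4, sr: 8.9, snh: 10.5}
early_spring:
  - {month: Jan, tmax: 14.5, tmin: 1.2, rain: 72.5, sr: 23.7, snh: 13.4}
  - {month: Feb, tmax: 18.7, tmin: 3.2, rain: 5.2, sr: 15.74, snh: 12.9}
  - {month: Mar, tmax: 24.6, tmin: 8.5, rain: 26.0, sr: 19.3, snh: 12.1}
  - {month: Apr, tmax: 23.0, tmin: 10.6, rain: 70.8, sr: 16.9, snh: 11.4}
  - {month: May, tmax: 27.6, tmin: 13.9, rain: 15.6, sr: 20.0, snh: 10.8}
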