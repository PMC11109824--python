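# Synthetic four-motif CD reference basis (mean residue ellipticity,
# deg cm^2 dmol^-1) constructed from Gaussian bands whose centres and
# magnitudes follow the canonical poly-peptide reference shapes for
# alpha-helix, beta-sheet, beta-turn and random coil. SYNTHETIC
# stand-in: not measured data; users fitting real spectra should
# supply their own measured basis.
wavelength_nm,helix,sheet,turn,coil
200.0,15645.2,25269.6,12525.7,-37064.3
200.5,11088.0,23526.6,13232.8,-34625.7
201.0,6643.6,21710.5,13840.3,-32000.0
201.5,2336.2,19851.7,14331.1,-29248.7
202.0,-1812.2,17978.6,14690.9,-26431.8
202.5,-5780.6,16116.0,14908.9,-23605.9
203.0,-9548.3,14284.7,14978.1,-20822.5
203.5,-13094.8,12501.1,14896.0,-18126.1
204.0,-16399.7,10776.7,14664.3,-15553.7
204.5,-19442.8,9118.3,14289.1,-13134.2
205.0,-22204.5,7528.2,13780.3,-10888.4
205.5,-24667.5,6004.3,13151.2,-8829.2
206.0,-26816.9,4540.9,12418.0,-6962.7
206.5,-28642.2,3129.5,11598.4,-5288.3
207.0,-30138.0,1759.4,10711.6,-3800.9
207.5,-31305.2,418.8,9776.7,-2490.9
208.0,-32151.8,-904.3,8812.3,-1346.0
208.5,-32693.2,-2221.0,7835.6,-351.9
209.0,-32952.5,-3540.7,6861.9,506.6
209.5,-32960.0,-4870.3,5904.1,1244.8
210.0,-32752.1,-6213.4,4972.4,1877.6
210.5,-32370.6,-7569.6,4074.2,2418.9
211.0,-31861.0,-8934.5,3214.2,2881.3
211.5,-31270.1,-10299.3,2394.6,3276.2
212.0,-30645.1,-11651.1,1615.1,3613.0
212.5,-30030.8,-12972.9,873.9,3899.9
213.0,-29468.2,-14245.0,167.3,4143.6
213.5,-28992.6,-15445.1,-508.9,4349.4
214.0,-28632.5,-16549.6,-1159.7,4521.5
214.5,-28408.5,-17534.7,-1790.0,4663.3
215.0,-28332.6,-18377.8,-2404.5,4777.1
215.5,-28408.0,-19058.4,-3007.0,4865.0
216.0,-28629.5,-19559.6,-3600.4,4928.2
216.5,-28984.2,-19868.5,-4186.5,4967.8
217.0,-29452.0,-19977.5,-4765.7,4984.9
217.5,-30006.9,-19884.4,-5337.2,4980.2
218.0,-30618.7,-19592.9,-5898.7,4954.4
218.5,-31254.2,-19112.3,-6446.7,4908.5
219.0,-31878.6,-18457.1,-6976.8,4843.4
219.5,-32457.1,-17646.4,-7483.6,4759.9
220.0,-32956.7,-16703.0,-7961.0,4659.4
220.5,-33346.6,-15652.5,-8402.7,4543.0
221.0,-33600.2,-14521.9,-8802.0,4412.0
221.5,-33695.3,-13338.8,-9152.6,4268.1
222.0,-33615.0,-12130.1,-9448.6,4112.7
222.5,-33348.1,-10921.2,-9684.9,3947.5
223.0,-32889.2,-9734.9,-9857.0,3774.1
223.5,-32238.5,-8591.0,-9962.0,3594.3
224.0,-31401.9,-7506.1,-9997.8,3409.7
224.5,-30390.1,-6493.0,-9963.9,3221.9
225.0,-29218.1,-5560.7,-9861.1,3032.6
225.5,-27904.9,-4714.9,-9691.7,2843.4
226.0,-26471.9,-3958.0,-9459.2,2655.5
226.5,-24942.7,-3289.5,-9168.3,2470.3
227.0,-23342.1,-2706.7,-8824.8,2289.2
227.5,-21695.0,-2205.0,-8435.4,2113.0
228.0,-20025.9,-1778.4,-8007.3,1942.8
228.5,-18358.3,-1420.1,-7548.4,1779.3
229.0,-16713.7,-1122.7,-7066.5,1623.3
229.5,-15111.5,-878.7,-6569.5,1475.1
230.0,-13568.6,-680.9,-6065.3,1335.3
230.5,-12099.2,-522.4,-5561.0,1204.0
231.0,-10714.3,-396.8,-5063.4,1081.3
231.5,-9422.4,-298.4,-4578.3,967.4
232.0,-8228.9,-222.2,-4111.1,862.1
232.5,-7136.9,-163.8,-3666.0,765.3
233.0,-6147.0,-119.5,-3246.5,676.7
233.5,-5257.8,-86.4,-2855.1,596.0
234.0,-4466.1,-61.8,-2493.5,522.9
234.5,-3767.4,-43.7,-2162.7,457.0
235.0,-3156.0,-30.7,-1862.7,397.8
235.5,-2625.5,-21.3,-1593.3,344.9
236.0,-2169.0,-14.6,-1353.4,297.9
236.5,-1779.6,-10.0,-1141.6,256.3
237.0,-1449.9,-6.7,-956.3,219.7
237.5,-1173.2,-4.5,-795.6,187.5
238.0,-942.7,-3.0,-657.3,159.5
238.5,-752.2,-1.9,-539.3,135.1
239.0,-596.1,-1.3,-439.4,114.0
239.5,-469.1,-0.8,-355.5,95.8
240.0,-366.6,-0.5,-285.7,80.2
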