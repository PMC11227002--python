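country,sex,quantity,expectancy,lower_95,upper_95,pct_of_le
costa_rica,male,none,6.2,5.5,7.0,25.6
costa_rica,male,one,6.6,5.6,7.5,26.9
costa_rica,male,dfmm,6.0,5.1,6.9,24.8
costa_rica,male,dmm,5.5,4.2,6.9,22.7
costa_rica,male,mmfree_le,12.8,11.1,14.5,52.5
costa_rica,male,mmle,11.5,9.3,13.8,47.5
costa_rica,male,le,24.3,22.9,25.8,100.0
costa_rica,female,none,2.5,1.9,3.0,9.9
costa_rica,female,one,7.5,6.6,8.5,29.9
costa_rica,female,dfmm,6.6,5.7,7.4,26.1
costa_rica,female,dmm,8.6,7.2,10.0,34.2
costa_rica,female,mmfree_le,10.0,8.5,11.5,39.8
costa_rica,female,mmle,15.2,12.9,17.4,60.2
costa_rica,female,le,25.1,23.3,26.9,100.0
mexico,male,none,4.9,4.4,5.5,21.4
mexico,male,one,6.6,5.8,7.3,28.7
mexico,male,dfmm,7.0,6.2,7.7,30.5
mexico,male,dmm,4.4,3.6,5.3,19.4
mexico,male,mmfree_le,11.5,10.2,12.8,50.1
mexico,male,mmle,11.4,9.8,13.0,49.9
mexico,male,le,22.9,21.8,24.0,100.0
mexico,female,none,2.5,2.3,2.8,9.9
mexico,female,one,5.6,5.2,6.1,22.1
mexico,female,dfmm,9.3,8.6,9.9,36.6
mexico,female,dmm,7.9,7.0,8.9,31.3
mexico,female,mmfree_le,8.1,7.5,8.9,32.1
mexico,female,mmle,17.2,15.6,18.8,67.9
mexico,female,le,25.4,24.4,26.3,100.0
united_states,male,none,1.4,1.3,1.5,6.8
united_states,male,one,3.2,3.0,3.3,15.3
united_states,male,dfmm,11.9,11.6,12.2,57.0
united_states,male,dmm,4.4,4.1,4.6,20.9
united_states,male,mmfree_le,4.6,4.3,4.8,22.1
united_states,male,mmle,16.3,15.7,16.8,77.9
united_states,male,le,20.8,20.5,21.2,100.0
united_states,female,none,1.3,1.2,1.4,5.6
united_states,female,one,3.3,3.1,3.4,14.1
united_states,female,dfmm,11.1,10.9,11.4,48.1
united_states,female,dmm,7.4,7.2,7.7,32.2
united_states,female,mmfree_le,4.6,4.3,4.8,19.7
united_states,female,mmle,18.5,18.1,19.1,80.3
united_states,female,le,23.1,22.8,23.4,100.0
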