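# Mean egg-to-adult development times (days) of two pupal parasitoids of the
# fall webworm reared at constant temperatures; n = 50 individuals per cell.
# Empty mean_dev_time_days = no emergence observed at that temperature.
species,sex,temperature_C,mean_dev_time_days,n
C_cunea,female,10,,50
C_cunea,female,15,115,50
C_cunea,female,20,48.8,50
C_cunea,female,25,23.13,50
C_cunea,female,30,21.50,50
C_cunea,male,10,,50
C_cunea,male,15,115,50
C_cunea,male,20,48,50
C_cunea,male,25,23.1,50
C_cunea,male,30,21.6,50
P_omnivorus,female,10,,50
P_omnivorus,female,15,,50
P_omnivorus,female,20,19.76,50
P_omnivorus,female,25,19.98,50
P_omnivorus,female,30,22.1,50
P_omnivorus,male,10,,50
P_omnivorus,male,15,,50
P_omnivorus,male,20,19.77,50
P_omnivorus,male,25,20.08,50
P_omnivorus,male,30,22.06,50
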